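"""TSV/JSON input and output.

Native table dialect: tab-separated, header row = feature ids, first
column = sample ids.  Ground truth, run manifests, and evaluation reports
are JSON.  Samples and features are always referenced by id, never by
position.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import ConditionParams, CountMatrix, EFMatrix, MixtureFit, partial_correlations
from .synthgen import ConditionTruth, GroundTruth

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_ef_table",
    "write_ef_table",
    "read_truth",
    "write_truth",
    "write_networks",
    "read_networks",
]


def read_otu_table(path) -> CountMatrix:
    """Read a samples x OTUs count table; rejects zero-read samples by name."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample or OTU ids")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(
                f"{path}: non-integer count at line {row + 2}, column {col!r}"
            )
    counts = df.to_numpy(dtype=np.int64)
    return CountMatrix(counts, [str(s) for s in df.index], [str(c) for c in df.columns])


def write_otu_table(X: CountMatrix, path) -> None:
    df = pd.DataFrame(X.counts, index=X.sample_ids, columns=X.otu_ids)
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_ef_table(
    path, count_matrix: CountMatrix | None = None, mapping: dict | None = None
) -> EFMatrix:
    """Read a samples x EFs table, optionally recoding ordinal categories.

    ``mapping`` maps category strings (e.g. Never..Daily) to numbers; it is
    never inferred.  When a count matrix is given, rows are aligned to its
    sample ids and unmatched samples are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample or EF ids")
    if mapping:
        df = df.replace(mapping).infer_objects(copy=False)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}; supply a mapping file"
            )
        df[col] = vals
        if float(vals.std()) == 0.0:
            warnings.warn(f"EF column {col!r} is constant across samples", RuntimeWarning)
    df.index = df.index.astype(str)
    if count_matrix is not None:
        want = [s for s in count_matrix.sample_ids if s in set(df.index)]
        dropped = len(df) - len(want)
        missing = [s for s in count_matrix.sample_ids if s not in set(df.index)]
        if missing:
            raise ValueError(f"EF table missing samples: {missing[:5]}")
        if dropped:
            warnings.warn(f"dropped {dropped} EF rows without count data", RuntimeWarning)
        df = df.loc[want]
    return EFMatrix(
        df.to_numpy(dtype=float), [str(s) for s in df.index], [str(c) for c in df.columns]
    )


def write_ef_table(M: EFMatrix, path) -> None:
    df = pd.DataFrame(M.values, index=M.sample_ids, columns=M.ef_ids)
    df.to_csv(path, sep="\t", index_label="sample_id")


def _mat(a) -> dict:
    a = np.asarray(a)
    return {"shape": list(a.shape), "data": a.ravel().tolist()}


def _unmat(d) -> np.ndarray:
    return np.asarray(d["data"], dtype=float).reshape(d["shape"])


def write_truth(truth: GroundTruth, path) -> None:
    doc = {
        "K": truth.K,
        "otu_ids": truth.otu_ids,
        "ef_ids": truth.ef_ids,
        "labels": truth.labels.tolist(),
        "alpha_clipped": bool(truth.alpha_clipped),
        "conditions": [
            {
                "B": _mat(c.B),
                "Theta": _mat(c.Theta),
                "B0": _mat(c.B0),
                "mu": _mat(c.mu),
                "Sigma": _mat(c.Sigma),
                "adjacency": _mat(c.adjacency),
            }
            for c in truth.conditions
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_truth(path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    conds = [
        ConditionTruth(
            B=_unmat(c["B"]),
            Theta=_unmat(c["Theta"]),
            B0=_unmat(c["B0"]).ravel(),
            mu=_unmat(c["mu"]).ravel(),
            Sigma=_unmat(c["Sigma"]),
            adjacency=_unmat(c["adjacency"]).astype(int),
        )
        for c in doc["conditions"]
    ]
    return GroundTruth(
        conds,
        np.asarray(doc["labels"], dtype=int),
        doc["otu_ids"],
        doc["ef_ids"],
        doc["alpha_clipped"],
    )


def write_networks(fit: MixtureFit, outdir, manifest: dict | None = None) -> None:
    """Write per-condition edge lists, parameters, and a run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"sample_id": fit.sample_ids, "condition": fit.assignments}
    ).to_csv(out / "assignments.tsv", sep="\t", index=False)
    for k, (params, kept) in enumerate(
        zip(fit.conditions, fit.kept_otus_per_condition), start=1
    ):
        cdir = out / f"condition_{k}"
        cdir.mkdir(exist_ok=True)
        rho = partial_correlations(params.Theta)
        rows = []
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                if rho[a, b] != 0.0:
                    rows.append((kept[a], kept[b], rho[a, b]))
        pd.DataFrame(rows, columns=["otu_a", "otu_b", "partial_correlation"]).to_csv(
            cdir / "otu_otu_edges.tsv", sep="\t", index=False
        )
        rows = []
        for q, ef in enumerate(fit.ef_ids):
            for p, otu in enumerate(kept):
                if params.B[q, p] != 0.0:
                    rows.append((ef, otu, params.B[q, p]))
        pd.DataFrame(rows, columns=["ef", "otu", "coefficient"]).to_csv(
            cdir / "ef_otu_edges.tsv", sep="\t", index=False
        )
        doc = {
            "weight": params.weight,
            "ebic": float(fit.ebic_per_condition[k - 1]),
            "kept_otus": kept,
            "ef_ids": fit.ef_ids,
            "B": _mat(params.B),
            "B_score": _mat(params.B_score) if params.B_score is not None else None,
            "Theta_score": _mat(params.Theta_score)
            if params.Theta_score is not None
            else None,
            "B0": _mat(params.B0),
            "Theta": _mat(params.Theta),
            "mu": _mat(params.mu),
            "Sigma": _mat(params.Sigma),
        }
        (cdir / "params.json").write_text(json.dumps(doc))
    (out / "manifest.json").write_text(json.dumps(manifest or {}, indent=2))


def read_networks(outdir) -> MixtureFit:
    out = Path(outdir)
    assign = pd.read_csv(out / "assignments.tsv", sep="\t")
    cdirs = sorted(out.glob("condition_*"), key=lambda p: int(p.name.split("_")[1]))
    conditions, kept, ebics = [], [], []
    otu_union: list[str] = []
    ef_ids: list[str] = []
    for cdir in cdirs:
        doc = json.loads((cdir / "params.json").read_text())
        conditions.append(
            ConditionParams(
                B=_unmat(doc["B"]),
                B0=_unmat(doc["B0"]).ravel(),
                Theta=_unmat(doc["Theta"]),
                mu=_unmat(doc["mu"]).ravel(),
                Sigma=_unmat(doc["Sigma"]),
                weight=doc["weight"],
                B_score=_unmat(doc["B_score"]) if doc.get("B_score") else None,
                Theta_score=_unmat(doc["Theta_score"])
                if doc.get("Theta_score")
                else None,
            )
        )
        kept.append(doc["kept_otus"])
        ebics.append(doc["ebic"])
        ef_ids = doc["ef_ids"]
        for o in doc["kept_otus"]:
            if o not in otu_union:
                otu_union.append(o)
    return MixtureFit(
        K=len(conditions),
        conditions=conditions,
        assignments=assign["condition"].to_numpy(),
        ebic_per_condition=np.asarray(ebics),
        kept_otus_per_condition=kept,
        sample_ids=[str(s) for s in assign["sample_id"]],
        otu_ids=otu_union,
        ef_ids=ef_ids,
    )
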