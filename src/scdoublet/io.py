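"""TSV and YAML input/output for count matrices, calls and parameters.

Count matrices are plain TSV with droplet identifiers in the first column
and a header row of locus identifiers.  Rows and columns are aligned by
label, never by position, so exports with shuffled orderings load
correctly.  Parameter files are YAML with keys ``beta``, ``alpha_fp``,
``alpha_fn``, ``s``, ``delta`` and ``mu`` (either a global
``[wt, het, hom]`` triple or a per-locus table).
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .model import DropletCall, ErrorModel, LocusPriors, ReadCounts
from .simulate import ClonePanel, SimTruth

__all__ = [
    "read_counts",
    "read_matrix_tsv",
    "write_counts",
    "write_calls",
    "read_calls",
    "write_truth",
    "read_truth",
    "write_panel",
    "read_params",
    "write_params",
]

PathLike = Union[str, Path]


def read_matrix_tsv(path: PathLike) -> pd.DataFrame:
    """One labelled integer matrix from TSV (first column = droplet ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in count matrix")
    return df.astype(np.int64)

def read_counts(alt_path: PathLike, total_path: PathLike) -> ReadCounts:
    """Load paired alt/total TSVs, aligning labels (error if sets differ)."""
    alt = read_matrix_tsv(alt_path)
    total = read_matrix_tsv(total_path)
    return ReadCounts.from_frames(alt, total)


def write_counts(counts: ReadCounts, alt_path: PathLike, total_path: PathLike) -> None:
    alt, total = counts.to_frames()
    alt.to_csv(alt_path, sep="\t", index_label="droplet_id")
    total.to_csv(total_path, sep="\t", index_label="droplet_id")


def write_calls(calls: Sequence[DropletCall], path: PathLike) -> None:
    """Calls TSV: droplet_id, score, posterior, call; floats at 6 sig digits."""
    df = pd.DataFrame(
        {
            "droplet_id": [c.droplet_id for c in calls],
            "score": [c.score for c in calls],
            "posterior": [c.posterior for c in calls],
            "call": [c.label for c in calls],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls(path: PathLike) -> List[DropletCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        DropletCall(
            droplet_id=row.droplet_id,
            z=int(row.call == "doublet"),
            score=float(row.score),
            posterior=float(row.posterior),
        )
        for row in df.itertuples()
    ]


def write_truth(truth: SimTruth, path: PathLike) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def read_truth(path: PathLike) -> SimTruth:
    return SimTruth.from_frame(pd.read_csv(path, sep="\t"))


def write_panel(panel: ClonePanel, path: PathLike) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_params(
    err: ErrorModel, priors: Optional[LocusPriors], path: PathLike
) -> None:
    """Serialise an error model (and optional per-locus priors) to YAML."""
    payload = {
        "beta": float(err.beta),
        "alpha_fp": float(err.alpha_fp),
        "alpha_fn": float(err.alpha_fn),
        "s": float(err.s),
    }
    if err.delta is not None:
        payload["delta"] = float(err.delta)
    if priors is not None:
        mu = priors.mu
        if np.allclose(mu, mu[0]):
            payload["mu"] = [float(x) for x in mu[0]]
        else:
            payload["mu"] = {
                str(locus): [float(x) for x in row]
                for locus, row in zip(priors.locus_ids, mu)
            }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_params(
    path: PathLike, locus_ids: Optional[Sequence] = None
) -> Tuple[ErrorModel, Optional[LocusPriors]]:
    """Load an error model and, if present, genotype priors from YAML.

    A global ``mu`` triple needs ``locus_ids`` to broadcast against; a
    per-locus ``mu`` table is reordered to ``locus_ids`` when given.
    """
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    err = ErrorModel(
        beta=float(payload["beta"]),
        alpha_fp=float(payload["alpha_fp"]),
        alpha_fn=float(payload["alpha_fn"]),
        s=float(payload["s"]),
        delta=float(payload["delta"]) if "delta" in payload else None,
    )
    priors = None
    mu = payload.get("mu")
    if isinstance(mu, dict):
        ids = list(mu) if locus_ids is None else list(locus_ids)
        try:
            rows = [mu[str(locus)] for locus in ids]
        except KeyError as e:
            raise KeyError(f"parameter file lacks mu for locus {e}") from e
        priors = LocusPriors(
            locus_ids=np.asarray(ids, dtype=object), mu=np.asarray(rows, dtype=float)
        )
    elif mu is not None:
        if locus_ids is None:
            raise ValueError("global mu triple requires locus_ids to broadcast")
        priors = LocusPriors.global_triple(mu, locus_ids)
    return err, priors
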