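"""Readers and writers for the pipeline's CSV and Newick artifacts.

CSV is the canonical matrix format: frequency matrices are landrace rows x
SNP columns, distance matrices are square with a labelled header/index.
Floating-point output uses 10 significant digits so reruns are
byte-comparable.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ancestry import AdmixtureCoefficients
from .diversity import DistanceMatrix
from .genotyping import PanelFrequencies
from .structure import Tree

FLOAT_FMT = "%.10g"


class ParseError(ValueError):
    """A malformed input file, with the offending cell named."""


def read_frequency_matrix(path) -> PanelFrequencies:
    """Read a landrace x SNP frequency CSV (first column = landrace ids)."""
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"duplicate landrace identifiers: {dups}")
    if df.columns.duplicated().any():
        raise ParseError("duplicate SNP identifiers")
    vals = df.apply(pd.to_numeric, errors="coerce")
    bad_text = df.notna() & vals.isna()
    if bad_text.any().any():
        r, c = np.argwhere(bad_text.to_numpy())[0]
        raise ParseError(
            f"non-numeric value {df.iat[r, c]!r} at ({df.index[r]}, {df.columns[c]})")
    arr = vals.to_numpy(dtype=float)
    out_of_range = np.isfinite(arr) & ((arr < 0) | (arr > 1))
    if out_of_range.any():
        r, c = np.argwhere(out_of_range)[0]
        raise ParseError(
            f"frequency {arr[r, c]} outside [0, 1] at ({df.index[r]}, {df.columns[c]})")
    return PanelFrequencies(vals.astype(float))


def write_frequency_matrix(panel: PanelFrequencies, path,
                           mask_path=None) -> None:
    panel.freq.to_csv(path, float_format=FLOAT_FMT)
    if mask_path is not None and panel.polymorphic is not None:
        panel.polymorphic.to_csv(mask_path)


def read_distance_matrix(path, metric: str = "MRD") -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    df.columns = df.columns.astype(df.index.dtype) if df.index.dtype != object else df.columns
    return DistanceMatrix(df, metric=metric)


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    d.values.to_csv(path, float_format=FLOAT_FMT)


def read_admixture(path) -> AdmixtureCoefficients:
    df = pd.read_csv(path, index_col=0)
    extra = [c for c in ("rss", "n_loci") if c in df.columns]
    rss = df["rss"] if "rss" in extra else None
    n_loci = df["n_loci"] if "n_loci" in extra else None
    coef = df.drop(columns=extra)
    return AdmixtureCoefficients(coef, rss=rss, n_loci=n_loci)


def write_admixture(admix: AdmixtureCoefficients, path) -> None:
    out = admix.coef.copy()
    if admix.rss is not None:
        out["rss"] = admix.rss
    if admix.n_loci is not None:
        out["n_loci"] = admix.n_loci
    out.to_csv(path, float_format=FLOAT_FMT)


def read_trial_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"landrace", "trial", "rep", "DT", "DS", "PH", "EH"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"trial records missing columns {sorted(missing)}")
    if "is_check" not in df.columns:
        df["is_check"] = False
    return df


def write_trial_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_newick(tree: Tree, path) -> None:
    """Write a tree as Newick with full-precision branch lengths.

    Labels containing reserved characters are quoted (handled by the
    underlying serializer).
    """
    Path(path).write_text(tree.newick() + "\n")


def read_newick(path) -> Tree:
    return Tree.from_newick(Path(path).read_text())
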