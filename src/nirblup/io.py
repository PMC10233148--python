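"""Readers and writers for the plain-text formats used across the pipeline.

Genotypes travel either as PLINK ``.raw``-style additive dosage tables
(FID/IID header plus one column per marker, ``NA`` for missing) or as a
plain delimited matrix (first column line id, one column per marker).
Phenotypes are long-format CSV with columns
``line_id, year, location, nursery, trait, value``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .grm import GRM, GenotypeMatrix

PHENOTYPE_COLUMNS = ["line_id", "year", "location", "nursery", "trait", "value"]

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a dosage matrix, auto-detecting PLINK .raw vs plain matrix."""
    path = str(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.readline().split()
        fmt = "raw" if first[:2] == ["FID", "IID"] else "matrix"
    if fmt == "raw":
        df = pd.read_csv(path, sep=r"\s+")
        meta = [c for c in _RAW_META if c in df.columns]
        markers = [c for c in df.columns if c not in meta]
        return GenotypeMatrix(
            line_ids=df["IID"].astype(str).tolist(),
            marker_ids=markers,
            dosages=df[markers].to_numpy(dtype=float),
        )
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return GenotypeMatrix(
        line_ids=df.index.astype(str).tolist(),
        marker_ids=[str(c) for c in df.columns],
        dosages=df.to_numpy(dtype=float),
    )


def write_genotypes(genotypes: GenotypeMatrix, path, fmt: str = "raw") -> None:
    path = str(path)
    if fmt == "raw":
        df = pd.DataFrame(
            {
                "FID": genotypes.line_ids,
                "IID": genotypes.line_ids,
                "PAT": 0,
                "MAT": 0,
                "SEX": 0,
                "PHENOTYPE": -9,
            }
        )
        dos = pd.DataFrame(
            genotypes.dosages, columns=genotypes.marker_ids, index=df.index
        )
        pd.concat([df, dos], axis=1).to_csv(path, sep=" ", index=False, na_rep="NA")
    elif fmt == "matrix":
        genotypes.to_frame().to_csv(path, sep="\t", index_label="line_id", na_rep="NA")
    else:
        raise DataError(f"unknown genotype format {fmt!r}")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype={"line_id": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"phenotype file lacks columns {missing}")
    df = df[PHENOTYPE_COLUMNS].copy()
    df["value"] = df["value"].astype(float)
    if not np.isfinite(df["value"]).all():
        raise DataError("phenotype values must be finite")
    for c in ("year", "location", "nursery", "trait"):
        df[c] = df[c].astype(str)
    return df.reset_index(drop=True)


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def read_grm(path) -> GRM:
    """Read a GRM from square TSV (header = line ids) or sparse i/j/value text."""
    with open(str(path)) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:3] == ["i", "j", "value"]:
        df = pd.read_csv(path, sep="\t", dtype={"i": str, "j": str})
        ids = sorted(set(df["i"]) | set(df["j"]))
        pos = {l: k for k, l in enumerate(ids)}
        n = len(ids)
        vals = np.zeros((n, n))
        ii = df["i"].map(pos).to_numpy()
        jj = df["j"].map(pos).to_numpy()
        vals[ii, jj] = df["value"].to_numpy()
        vals[jj, ii] = df["value"].to_numpy()
        return GRM(ids, vals)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GRM([str(c) for c in df.columns], df.to_numpy(dtype=float))


def write_grm(grm: GRM, path, fmt: str = "square") -> None:
    path = str(path)
    if fmt == "square":
        grm.to_frame().to_csv(path, sep="\t", index_label="line_id")
    elif fmt == "sparse":
        n = grm.n_lines
        iu = np.triu_indices(n)
        df = pd.DataFrame(
            {
                "i": [grm.line_ids[a] for a in iu[0]],
                "j": [grm.line_ids[b] for b in iu[1]],
                "value": grm.values[iu],
            }
        )
        df.to_csv(path, sep="\t", index=False)
    else:
        raise DataError(f"unknown GRM format {fmt!r}")


def read_blues(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"line_id": str})
    needed = {"line_id", "trait", "blue"}
    if not needed.issubset(df.columns):
        raise DataError(f"BLUE file lacks columns {sorted(needed - set(df.columns))}")
    return df


def write_blues(blues: pd.DataFrame, path) -> None:
    blues.to_csv(path, index=False)


def blues_to_series(blues: pd.DataFrame, trait: str | None = None) -> pd.Series:
    """Collapse a BLUE table to a Series of adjusted values indexed by line id."""
    df = blues
    if trait is not None:
        df = df[df["trait"] == trait]
    if df["line_id"].duplicated().any():
        raise DataError("duplicate line ids in BLUE table for one trait")
    return pd.Series(df["blue"].to_numpy(), index=df["line_id"].astype(str), name="blue")
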