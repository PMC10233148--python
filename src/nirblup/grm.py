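"""Genomic relationship matrix construction and inspection.

The GRM is the realized-kinship matrix of VanRaden's first method:
dosages are centered at twice the observed allele frequency and the
cross-product is scaled by ``2 * sum_j p_j (1 - p_j)`` so that, for a
population in Hardy-Weinberg proportions at the centering frequencies,
the expected diagonal is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ComputationError, DataError

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "compute_allele_freq",
    "build_grm",
    "grm_condition",
    "pca_grm",
]


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with codes 0/1/2; missing as NaN.

    Parameters
    ----------
    line_ids : ordered unique line identifiers (length n).
    marker_ids : ordered marker identifiers (length m).
    dosages : (n, m) float array with values in {0, 1, 2} or NaN.
    """

    line_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.line_ids) or m != len(self.marker_ids):
            raise DataError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != n:
            raise DataError("duplicate line ids in genotype matrix")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = np.unique(vals[~np.isin(vals, (0.0, 1.0, 2.0))])
            raise DataError(f"dosage codes outside {{0,1,2}}: {bad[:5]}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.line_ids, columns=self.marker_ids)


@dataclass
class GRM:
    """Symmetric genomic relationship matrix over a set of lines."""

    line_ids: list[str]
    values: np.ndarray
    ridge_applied: float = 0.0
    #: markers retained after the MAF filter (informational)
    n_markers_used: int = field(default=0)

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise DataError("GRM must be square and match line_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DataError("GRM is not symmetric to 1e-10")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def index_of(self, lines) -> np.ndarray:
        pos = {l: i for i, l in enumerate(self.line_ids)}
        try:
            return np.array([pos[str(l)] for l in lines], dtype=int)
        except KeyError as exc:
            raise DataError(f"line id not present in GRM: {exc.args[0]!r}") from exc

    def subset(self, lines) -> "GRM":
        idx = self.index_of(lines)
        return GRM(
            [self.line_ids[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            ridge_applied=self.ridge_applied,
            n_markers_used=self.n_markers_used,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids)


def compute_allele_freq(genotypes: GenotypeMatrix) -> np.ndarray:
    """Observed alternate-allele frequency per marker.

    ``p_j = sum(non-missing dosages at j) / (2 * non-missing count)``.

    Raises
    ------
    DataError
        If any marker has no non-missing call (the offending ids are listed).
    """
    d = genotypes.dosages
    n_obs = np.sum(~np.isnan(d), axis=0)
    if (n_obs == 0).any():
        bad = [genotypes.marker_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise DataError(f"markers with all calls missing: {bad}")
    return np.nansum(d, axis=0) / (2.0 * n_obs)


def build_grm(
    genotypes: GenotypeMatrix,
    freq: np.ndarray | None = None,
    min_maf: float = 0.0,
) -> GRM:
    """VanRaden (method 1) GRM: ``G = W W' / (2 * sum p(1-p))``.

    ``W`` holds dosages centered at ``2p``; missing dosages are replaced by
    the marker mean (zero after centering). Markers with minor-allele
    frequency below ``min_maf`` are dropped before scaling.
    """
    if freq is None:
        freq = compute_allele_freq(genotypes)
    freq = np.asarray(freq, dtype=float)
    if freq.shape != (genotypes.n_markers,):
        raise DataError("frequency vector is not aligned with markers")
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= min_maf if min_maf > 0 else np.ones_like(maf, dtype=bool)
    p = freq[keep]
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise ComputationError(
            "all retained markers are monomorphic; GRM scaling denominator is zero"
        )
    W = genotypes.dosages[:, keep] - 2.0 * p
    W = np.where(np.isnan(W), 0.0, W)
    G = W @ W.T / denom
    G = (G + G.T) / 2.0  # enforce exact symmetry against round-off
    return GRM(genotypes.line_ids, G, ridge_applied=0.0, n_markers_used=int(keep.sum()))


def grm_condition(grm: GRM, ridge: float = 1e-6) -> GRM:
    """Add a diagonal ridge only if the smallest eigenvalue is below 1e-8.

    Returns a new GRM; ``ridge_applied`` records the amount added (0 when the
    matrix was already safely positive definite).
    """
    if ridge < 0:
        raise ComputationError("ridge must be non-negative")
    w = np.linalg.eigvalsh(grm.values)
    if w.min() >= 1e-8:
        return GRM(grm.line_ids, grm.values.copy(), 0.0, grm.n_markers_used)
    return GRM(
        grm.line_ids,
        grm.values + ridge * np.eye(grm.n_lines),
        ridge_applied=float(ridge),
        n_markers_used=grm.n_markers_used,
    )


def pca_grm(grm: GRM, n_components: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of G by eigen-decomposition.

    Scores are eigenvectors scaled by ``sqrt(eigenvalue)``; the fraction of
    variance explained by component k is ``eigenvalue_k / trace(G)``.
    Eigenvalues are returned in non-increasing order.
    """
    if n_components > grm.n_lines:
        raise ComputationError("n_components exceeds the number of lines")
    if not np.isfinite(grm.values).all():
        raise ComputationError("GRM contains non-finite entries")
    w, v = np.linalg.eigh(grm.values)
    order = np.argsort(w)[::-1][:n_components]
    w = w[order]
    v = v[:, order]
    scores = v * np.sqrt(np.clip(w, 0.0, None))
    explained = w / np.trace(grm.values)
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return pd.DataFrame(scores, index=grm.line_ids, columns=cols), explained
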