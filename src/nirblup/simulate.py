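"""Synthetic breeding-program data with known ground truth.

The generator emulates the data structure of a commercial wheat quality
breeding program: each line enters the program in one year ("cohort"),
is measured for an expensive end-product (EP) quality trait and a cheap
NIR-predicted proxy of it, and the two traits share genetic signal with
a configurable genetic correlation. Line counts per year and per trait
can be made as unbalanced as real programs are (e.g. a few hundred EP
assays vs thousands of NIR predictions per year).

Breeding values are generated through marker effects (``u = W a``) and
then rescaled so the *realized* genetic variances and correlation hit
their targets exactly, which makes ground truth exact at any sample
size. A small set of check lines is grown in every trial of every year
so that the trial design stays connected for fixed-effect adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .grm import GenotypeMatrix
from .io import PHENOTYPE_COLUMNS

__all__ = [
    "TRAIT_EP",
    "TRAIT_NIR",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "apply_missingness",
    "simulate_dataset",
]

TRAIT_EP = "EP"
TRAIT_NIR = "NIR"


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``maf_range`` is the interval the per-marker alternate-allele frequency
    is drawn from. Values above 0.5 are permitted (the alternate allele is
    then the major allele), which allows degenerate fixed-marker setups;
    ordinary use keeps the range inside (0, 0.5].

    ``lines_per_year_ep`` / ``lines_per_year_nir`` give, per year, how many
    lines keep records for each trait; ``None`` keeps every cohort line.
    Years with more NIR than EP lines create the NIR-only training pool the
    multi-trait scenarios exploit; the opposite pattern is equally valid.
    """

    n_lines: int = 400
    n_markers: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_ep: float = 0.6
    h2_nir: float = 0.7
    r_g: float = 0.8
    r_e: float = 0.3
    years: Sequence[str] = field(default_factory=lambda: [str(y) for y in range(2012, 2020)])
    lines_per_year_ep: Sequence[int] | None = None
    lines_per_year_nir: Sequence[int] | None = None
    n_trials_per_year: int = 3
    trial_effect_sd: float = 1.0
    seed: int = 0
    # structural knobs beyond the headline parameters
    mean_ep: float = 0.0
    mean_nir: float = 0.0
    n_check_lines: int = 2
    reps_per_line: int = 2
    n_families: int = 0
    #: assign year cohorts in family order instead of at random, so each
    #: breeding cycle introduces new families (makes forward prediction
    #: genuinely harder than cross-validation, as in real programs)
    cohorts_by_family: bool = False

    def __post_init__(self) -> None:
        if self.n_lines < 2 or self.n_markers < 1:
            raise ConfigurationError("need n_lines >= 2 and n_markers >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError(f"invalid maf_range {self.maf_range}")
        for name in ("h2_ep", "h2_nir"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in ("r_g", "r_e"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [-1, 1]")
        self.years = [str(y) for y in self.years]
        for name in ("lines_per_year_ep", "lines_per_year_nir"):
            counts = getattr(self, name)
            if counts is not None:
                counts = [int(c) for c in counts]
                if len(counts) != len(self.years):
                    raise ConfigurationError(f"{name} length must match years")
                if any(c < 0 for c in counts):
                    raise ConfigurationError(f"{name} has negative counts")
                setattr(self, name, counts)
        if self.n_trials_per_year < 1:
            raise ConfigurationError("n_trials_per_year must be >= 1")
        if self.n_check_lines < 0 or self.n_check_lines >= self.n_lines:
            raise ConfigurationError("n_check_lines must be in [0, n_lines)")
        # implied 2x2 covariance matrices; PSD holds whenever |r| <= 1 but the
        # check stays explicit so future covariance parametrizations fail loudly
        for C in (self.genetic_cov(), self.residual_cov()):
            if np.linalg.eigvalsh(C).min() < -1e-12:
                raise ConfigurationError("implied trait covariance is not PSD")

    def genetic_cov(self) -> np.ndarray:
        c = self.r_g * np.sqrt(self.h2_ep * self.h2_nir)
        return np.array([[self.h2_ep, c], [c, self.h2_nir]])

    def residual_cov(self) -> np.ndarray:
        ve, vn = 1.0 - self.h2_ep, 1.0 - self.h2_nir
        c = self.r_e * np.sqrt(ve * vn)
        return np.array([[ve, c], [c, vn]])

    def cohort_sizes(self) -> list[int]:
        """Lines entering per year (before per-trait missingness)."""
        n_avail = self.n_lines - self.n_check_lines
        if self.lines_per_year_ep is None and self.lines_per_year_nir is None:
            base = n_avail // len(self.years)
            sizes = [base] * len(self.years)
            for k in range(n_avail - base * len(self.years)):
                sizes[k] += 1
            return sizes
        ep = self.lines_per_year_ep or [0] * len(self.years)
        nir = self.lines_per_year_nir or [0] * len(self.years)
        sizes = [max(a, b) for a, b in zip(ep, nir)]
        if sum(sizes) > n_avail:
            raise ConfigurationError(
                f"yearly cohorts need {sum(sizes)} lines but only "
                f"{n_avail} non-check lines are configured"
            )
        return sizes


@dataclass
class SimulationTruth:
    """Ground-truth ledger for parameter-recovery tests."""

    true_bv_ep: pd.Series
    true_bv_nir: pd.Series
    true_params: dict
    marker_effects: pd.DataFrame
    trial_effects: pd.Series
    line_year: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "line_id": self.true_bv_ep.index,
                "true_bv_ep": self.true_bv_ep.to_numpy(),
                "true_bv_nir": self.true_bv_nir.to_numpy(),
            }
        )


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a lines x markers dosage matrix.

    Per marker, the alternate-allele frequency is uniform on ``maf_range``
    and dosages are binomial(2, p) per line. With ``n_families > 0`` each
    family shares one parental gamete per marker (half-sib blocks), creating
    within-family relatedness of about 1/4 on the GRM scale.
    """
    rng = _rngs(config.seed, 4)[0]
    n, m = config.n_lines, config.n_markers
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    # allow a degenerate range hitting exactly 1.0 (fixation checks)
    if config.maf_range[0] == config.maf_range[1]:
        p[:] = config.maf_range[0]
    if config.n_families > 0:
        fam = np.repeat(np.arange(config.n_families), int(np.ceil(n / config.n_families)))[:n]
        parental = rng.binomial(1, p, size=(config.n_families, m)).astype(float)
        own = rng.binomial(1, p, size=(n, m)).astype(float)
        dos = parental[fam] + own
    else:
        dos = rng.binomial(2, p, size=(n, m)).astype(float)
    width = len(str(n))
    ids = [f"CHK{i:03d}" for i in range(config.n_check_lines)] + [
        f"L{i:0{width}d}" for i in range(n - config.n_check_lines)
    ]
    markers = [f"M{j}" for j in range(m)]
    return GenotypeMatrix(ids, markers, dos)


def _psd_sqrt(C: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(C)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T


def _inv_sqrt(S: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(S)
    if w.min() <= 1e-12 * max(w.max(), 1.0):
        raise ConfigurationError(
            "realized genetic covariance is singular; increase n_markers or n_lines"
        )
    return v @ np.diag(1.0 / np.sqrt(w)) @ v.T


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate EP/NIR trial records and the matching truth ledger.

    Breeding values are ``u = W a`` with dosages centered at observed
    frequencies; the 2 x m effect matrix starts from a bivariate normal and
    is linearly rescaled so the realized 2x2 genetic covariance equals the
    target exactly. Residual pairs are drawn per (line, trial) with the
    configured residual correlation; trial effects are i.i.d. normal per
    (year, trial) and shared by every record in the trial.

    When ``lines_per_year_*`` counts are configured the returned table
    already has :func:`apply_missingness` applied.
    """
    if np.isnan(genotypes.dosages).any():
        raise DataError("simulate_phenotypes requires complete genotypes")
    _, rng_eff, rng_res, rng_layout = _rngs(config.seed, 4)
    n, m = genotypes.n_lines, genotypes.n_markers

    p_hat = genotypes.dosages.mean(axis=0) / 2.0
    W = genotypes.dosages - 2.0 * p_hat  # columns sum to zero exactly

    C_g = config.genetic_cov()
    a_raw = rng_eff.standard_normal((m, 2))
    u_raw = W @ a_raw
    if C_g.max() <= 0:
        effects = np.zeros((m, 2))
    else:
        S = np.cov(u_raw, rowvar=False, ddof=1)
        effects = a_raw @ _inv_sqrt(S) @ _psd_sqrt(C_g)
    u = W @ effects
    bv_ep = pd.Series(u[:, 0], index=genotypes.line_ids, name="true_bv_ep")
    bv_nir = pd.Series(u[:, 1], index=genotypes.line_ids, name="true_bv_nir")

    # cohorts: checks first, the rest shuffled into year blocks
    checks = genotypes.line_ids[: config.n_check_lines]
    others = list(genotypes.line_ids[config.n_check_lines :])
    if not config.cohorts_by_family:
        rng_layout.shuffle(others)
    sizes = config.cohort_sizes()
    cohorts: dict[str, list[str]] = {}
    start = 0
    for year, size in zip(config.years, sizes):
        cohorts[year] = others[start : start + size]
        start += size

    trial_eff = {}
    for year in config.years:
        for t in range(config.n_trials_per_year):
            trial_eff[(year, t)] = rng_layout.normal(0.0, config.trial_effect_sd)

    L_e = _psd_sqrt(config.residual_cov())
    rows: list[tuple] = []
    line_year: dict[str, str] = {}

    def emit(line: str, year: str, trial: int) -> None:
        e = L_e @ rng_res.standard_normal(2)
        te = trial_eff[(year, trial)]
        loc, nur = f"LOC{trial + 1}", "MAIN"
        rows.append(
            (line, year, loc, nur, TRAIT_EP, config.mean_ep + bv_ep[line] + te + e[0])
        )
        rows.append(
            (line, year, loc, nur, TRAIT_NIR, config.mean_nir + bv_nir[line] + te + e[1])
        )

    k = config.n_trials_per_year
    reps = min(config.reps_per_line, k)
    for year in config.years:
        for line in cohorts[year]:
            line_year[line] = year
            for trial in rng_layout.choice(k, size=reps, replace=False):
                emit(line, year, int(trial))
        for line in checks:
            line_year.setdefault(line, year)
            for trial in range(k):
                emit(line, year, trial)

    table = pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
    truth = SimulationTruth(
        true_bv_ep=bv_ep,
        true_bv_nir=bv_nir,
        true_params={
            "h2_ep": config.h2_ep,
            "h2_nir": config.h2_nir,
            "r_g": config.r_g,
            "r_e": config.r_e,
            "genetic_cov": C_g.tolist(),
            "residual_cov": config.residual_cov().tolist(),
            "trial_effect_sd": config.trial_effect_sd,
        },
        marker_effects=pd.DataFrame(
            effects, index=genotypes.marker_ids, columns=["effect_ep", "effect_nir"]
        ),
        trial_effects=pd.Series(
            {f"{y}_LOC{t + 1}_MAIN": v for (y, t), v in trial_eff.items()}
        ),
        line_year=pd.Series(line_year, name="year"),
    )
    if config.lines_per_year_ep is not None or config.lines_per_year_nir is not None:
        table = apply_missingness(table, config)
    return table, truth


def apply_missingness(table: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Thin the record table to the configured per-year line counts.

    Counts are numbers of distinct lines retained per (year, trait), the way
    breeding programs tabulate them. Selection is nested so that when a year
    has fewer EP than NIR lines, every EP line also keeps its NIR records
    (and vice versa) — the double-phenotyped overlap the paired multi-trait
    scenario trains on. Check lines are preferentially retained because they
    are what keeps the trial design connected.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    ep_counts = config.lines_per_year_ep
    nir_counts = config.lines_per_year_nir
    keep_mask = pd.Series(True, index=table.index)

    for yi, year in enumerate(config.years):
        in_year = table["year"] == year
        avail = {
            tr: sorted(table.loc[in_year & (table["trait"] == tr), "line_id"].unique())
            for tr in (TRAIT_EP, TRAIT_NIR)
        }
        want = {
            TRAIT_EP: len(avail[TRAIT_EP]) if ep_counts is None else ep_counts[yi],
            TRAIT_NIR: len(avail[TRAIT_NIR]) if nir_counts is None else nir_counts[yi],
        }
        for tr in (TRAIT_EP, TRAIT_NIR):
            if want[tr] > len(avail[tr]):
                raise ConfigurationError(
                    f"year {year}: requested {want[tr]} {tr} lines but only "
                    f"{len(avail[tr])} are available"
                )
        # choose the larger trait's set first, then nest the smaller inside it
        big, small = (
            (TRAIT_NIR, TRAIT_EP) if want[TRAIT_NIR] >= want[TRAIT_EP] else (TRAIT_EP, TRAIT_NIR)
        )

        def pick(pool: list[str], count: int) -> list[str]:
            checks = [l for l in pool if l.startswith("CHK")]
            rest = [l for l in pool if not l.startswith("CHK")]
            take_checks = checks[: min(count, len(checks))]
            extra = count - len(take_checks)
            chosen = list(rng.choice(rest, size=extra, replace=False)) if extra else []
            return take_checks + chosen

        kept_big = pick(avail[big], want[big])
        pool_small = [l for l in kept_big if l in set(avail[small])]
        if want[small] <= len(pool_small):
            kept_small = pick(pool_small, want[small])
        else:  # smaller trait needs lines outside the bigger set (EP > NIR years)
            outside = [l for l in avail[small] if l not in set(kept_big)]
            kept_small = pool_small + pick(outside, want[small] - len(pool_small))
        kept = {big: set(kept_big), small: set(kept_small)}
        for tr in (TRAIT_EP, TRAIT_NIR):
            mask = in_year & (table["trait"] == tr) & ~table["line_id"].isin(kept[tr])
            keep_mask[table.index[mask]] = False

    return table[keep_mask].reset_index(drop=True)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimulationTruth]:
    """Convenience wrapper: genotypes plus phenotypes plus truth."""
    geno = simulate_genotypes(config)
    table, truth = simulate_phenotypes(geno, config)
    return geno, table, truth
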