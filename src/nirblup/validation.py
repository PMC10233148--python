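"""Cross-validation and forward-prediction schemes for genomic prediction.

Accuracy is always the Pearson correlation between the held-out lines'
adjusted phenotypes (BLUEs) and their GEBVs. Folds are drawn over
*lines*, never records, so a line's information cannot leak into its own
prediction through a second record.

Scenarios govern which NIR-predicted records accompany the end-product
training data:

S0
    single-trait baseline; no NIR data.
S1
    paired design: training restricted to non-validation lines that carry
    both traits; the validation lines' NIR records are removed too.
S2
    S1 plus every NIR-only line (the cheap mass-phenotyped pool) in the
    NIR training set.
S3
    S2 plus the validation candidates' own NIR records — the "NIR early,
    assay later" breeding use case.

Forward prediction trains on all lines first observed up to year k and
predicts end-product phenotypes of lines first observed in year k+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConvergenceError, DataError
from .greml import FitOptions, fit_bivariate, fit_single_trait
from .grm import GRM

__all__ = [
    "SCENARIOS",
    "MaskPlan",
    "ScenarioSplit",
    "AccuracyReport",
    "make_folds",
    "apply_scenario",
    "run_cv",
    "forward_split",
    "run_forward",
]

SCENARIOS = ("S0", "S1", "S2", "S3")


@dataclass
class MaskPlan:
    """Line-to-fold assignments for ``repeats`` independent k-fold rounds."""

    fold_assignments: list[dict[str, int]]  # one dict per repeat: line -> fold (1..k)
    k: int
    repeats: int
    seed: int

    def validation_lines(self, repeat: int, fold: int) -> list[str]:
        fa = self.fold_assignments[repeat]
        return sorted(l for l, f in fa.items() if f == fold)


@dataclass
class ScenarioSplit:
    train_ep: pd.Series
    train_nir: pd.Series
    validation_truth: pd.Series


@dataclass
class AccuracyReport:
    folds: pd.DataFrame  # scenario, repeat, fold, n_validation, accuracy, converged
    by_year: pd.DataFrame | None = None  # forward runs: mode, test_year, accuracy, n

    def summary(self) -> pd.DataFrame:
        ok = self.folds[self.folds["converged"]]
        g = ok.groupby("scenario")["accuracy"]
        out = pd.DataFrame(
            {"mean": g.mean(), "sd": g.std(ddof=1), "n_folds": g.size()}
        )
        failed = (
            self.folds[~self.folds["converged"]].groupby("scenario").size()
        )
        out["n_failed"] = failed.reindex(out.index).fillna(0).astype(int)
        return out

    def to_json_dict(self) -> dict:
        d = {"per_scenario": self.summary().round(6).to_dict(orient="index")}
        if self.by_year is not None:
            d["forward"] = {
                "per_year": self.by_year.round(6).to_dict(orient="records"),
                "mean": float(self.by_year["accuracy"].mean()),
            }
        return d


def make_folds(lines, k: int = 5, repeats: int = 10, seed: int = 0) -> MaskPlan:
    """Fresh random near-equal partition of the lines for every repeat."""
    lines = [str(l) for l in lines]
    if len(set(lines)) != len(lines):
        raise DataError("duplicate line ids passed to make_folds")
    if k < 2:
        raise ConfigurationError("need at least 2 folds")
    if len(lines) < k:
        raise ConfigurationError(f"{len(lines)} lines cannot fill {k} folds")
    assignments = []
    for ss in np.random.SeedSequence(seed).spawn(repeats):
        rng = np.random.default_rng(ss)
        order = list(lines)
        rng.shuffle(order)
        fa = {}
        for pos, line in enumerate(order):
            fa[line] = pos % k + 1
        assignments.append(fa)
    return MaskPlan(fold_assignments=assignments, k=k, repeats=repeats, seed=seed)


def apply_scenario(
    scenario: str,
    plan: MaskPlan,
    repeat: int,
    fold: int,
    blues_ep: pd.Series,
    blues_nir: pd.Series,
) -> ScenarioSplit:
    """Build masked training sets for one (scenario, repeat, fold).

    The validation truth never enters any training structure; this is
    asserted on every call and raises on violation.
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    val = plan.validation_lines(repeat, fold)
    missing = [l for l in val if l not in blues_ep.index]
    if missing:
        raise DataError(f"validation lines without end-product phenotype: {missing}")
    val_set = set(val)
    ep_lines = set(blues_ep.index)
    nir_lines = set(blues_nir.index) if blues_nir is not None else set()
    both = ep_lines & nir_lines

    if scenario == "S0":
        train_ep = blues_ep.drop(index=val)
        train_nir = pd.Series(dtype=float)
    elif scenario == "S1":
        keep = sorted(both - val_set)
        train_ep = blues_ep[blues_ep.index.isin(keep)]
        train_nir = blues_nir[blues_nir.index.isin(keep)]
    else:  # S2 / S3
        keep = sorted(both - val_set)
        train_ep = blues_ep[blues_ep.index.isin(keep)]
        nir_keep = (nir_lines - ep_lines) | (both - val_set)
        if scenario == "S3":
            nir_keep |= val_set & nir_lines
        train_nir = blues_nir[blues_nir.index.isin(sorted(nir_keep))]

    if val_set & set(train_ep.index):
        raise DataError(
            "internal consistency failure: validation end-product values "
            "leaked into training"
        )
    return ScenarioSplit(
        train_ep=train_ep,
        train_nir=train_nir,
        validation_truth=blues_ep[val],
    )


def _accuracy(gebv: pd.Series, truth: pd.Series) -> float:
    g = gebv[truth.index].to_numpy(dtype=float)
    t = truth.to_numpy(dtype=float)
    if len(t) < 3 or np.std(g) == 0 or np.std(t) == 0:
        return np.nan
    return float(np.corrcoef(g, t)[0, 1])


def _fit_and_score(split: ScenarioSplit, grm: GRM, options: FitOptions):
    """Fit the appropriate GREML model and score the validation lines."""
    if len(split.train_nir) == 0:
        fit = fit_single_trait(split.train_ep, grm, options)
        gebv = fit.gebv
    else:
        fit = fit_bivariate(split.train_ep, split.train_nir, grm, options)
        gebv = fit.gebv_ep
    return _accuracy(gebv, split.validation_truth), fit


def run_cv(
    blues_ep: pd.Series,
    blues_nir: pd.Series,
    grm: GRM,
    plan: MaskPlan,
    scenarios=SCENARIOS,
    options: FitOptions | None = None,
) -> AccuracyReport:
    """Fivefold x repeats cross-validated prediction accuracy per scenario.

    Folds whose GREML fit fails to converge are recorded with
    ``converged=False`` and excluded from the summary means.
    """
    options = options or FitOptions(tol=1e-5, max_iter=60)
    rows = []
    for scenario in scenarios:
        for rep in range(plan.repeats):
            for fold in range(1, plan.k + 1):
                split = apply_scenario(scenario, plan, rep, fold, blues_ep, blues_nir)
                try:
                    acc, _ = _fit_and_score(split, grm, options)
                    ok = True
                except ConvergenceError:
                    acc, ok = np.nan, False
                rows.append(
                    (scenario, rep, fold, len(split.validation_truth), acc, ok)
                )
    folds = pd.DataFrame(
        rows,
        columns=["scenario", "repeat", "fold", "n_validation", "accuracy", "converged"],
    )
    return AccuracyReport(folds=folds)


def forward_split(
    blues_ep: pd.Series,
    blues_nir: pd.Series,
    line_years: pd.Series,
    train_years,
    test_year: str,
    mode: str = "multi",
) -> ScenarioSplit:
    """Training/validation split for one forward-prediction step.

    ``line_years`` maps each line to its first observation year; a line seen
    in both periods therefore belongs to training and is excluded from
    validation.
    """
    train_years = {str(y) for y in train_years}
    test_year = str(test_year)
    if test_year in train_years:
        raise ConfigurationError("test year cannot be part of the training years")
    ly = line_years.astype(str)
    train_lines = set(ly.index[ly.isin(train_years)])
    val_lines = sorted(
        set(ly.index[ly == test_year]) & set(blues_ep.index) - train_lines
    )
    if not val_lines:
        raise DataError(f"no validation lines with end-product data in {test_year}")
    train_ep = blues_ep[blues_ep.index.isin(train_lines)]
    if mode == "multi":
        train_nir = blues_nir[blues_nir.index.isin(train_lines)]
    elif mode == "single":
        train_nir = pd.Series(dtype=float)
    else:
        raise ConfigurationError(f"unknown forward mode {mode!r}")
    if set(val_lines) & set(train_ep.index):
        raise DataError("validation lines leaked into forward training")
    return ScenarioSplit(
        train_ep=train_ep,
        train_nir=train_nir,
        validation_truth=blues_ep[val_lines],
    )


def run_forward(
    blues_ep: pd.Series,
    blues_nir: pd.Series,
    grm: GRM,
    line_years: pd.Series,
    test_years,
    mode: str = "multi",
    options: FitOptions | None = None,
) -> AccuracyReport:
    """Year-wise forward prediction: train on all earlier years, predict one.

    For each test year the training set is every line first observed in a
    strictly earlier year (end-product always; NIR too when
    ``mode='multi'``). Reports per-year accuracy and their mean.
    """
    options = options or FitOptions(tol=1e-5, max_iter=60)
    all_years = sorted(set(line_years.astype(str)))
    rows = []
    for test_year in [str(y) for y in test_years]:
        train_years = [y for y in all_years if y < test_year]
        if len(train_years) < 2:
            raise ConfigurationError(
                f"need at least 2 training years before {test_year}"
            )
        split = forward_split(
            blues_ep, blues_nir, line_years, train_years, test_year, mode
        )
        try:
            acc, _ = _fit_and_score(split, grm, options)
            ok = True
        except ConvergenceError:
            acc, ok = np.nan, False
        rows.append((mode, test_year, len(split.validation_truth), acc, ok))
    by_year = pd.DataFrame(
        rows, columns=["mode", "test_year", "n_validation", "accuracy", "converged"]
    )
    folds = by_year.rename(columns={"test_year": "fold"}).assign(
        scenario=f"forward_{mode}", repeat=0
    )[["scenario", "repeat", "fold", "n_validation", "accuracy", "converged"]]
    return AccuracyReport(folds=folds, by_year=by_year)
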