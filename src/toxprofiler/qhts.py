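"""Quantitative high-throughput screening (qHTS) concentration-response analysis.

Raw plate reads are normalized against the in-plate positive control and
DMSO-only wells, corrected for plate-position background, fitted to a
four-parameter Hill equation, and summarized as a curve class (1.1-4) and a
signed curve rank in [-9, 9].  Triplicate runs of the same compound are
reduced to a reproducibility call, and per-assay call rates to a single
reproducibility score (grade A > 90, grade B 80-90).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

AssayMode = Literal["agonist", "antagonist"]

#: rank magnitude per curve class before the potency bonus
_CLASS_RANK = {"1.1": 8, "2.1": 6, "1.2": 5, "2.2": 3, "3": 1, "4": 0}

#: AC50 below this concentration (molar) earns a +1 rank bonus
POTENCY_BONUS_AC50 = 1e-6


class DegenerateControlsError(ValueError):
    """Positive-control and DMSO medians coincide; % activity is undefined."""


@dataclass(frozen=True)
class RawTitration:
    """One compound's raw concentration series with plate-control context."""

    compound_id: str
    concentrations: np.ndarray  # molar, strictly increasing
    raw_reads: np.ndarray  # arbitrary signal units
    pos_control_median: float
    dmso_median: float
    assay_mode: AssayMode = "agonist"

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        reads = np.asarray(self.raw_reads, dtype=float)
        if conc.size < 4:
            raise ValueError("a titration needs at least 4 concentrations")
        if conc.size != reads.size:
            raise ValueError("concentrations and raw_reads differ in length")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.pos_control_median == self.dmso_median:
            raise DegenerateControlsError(
                "positive-control and DMSO medians are equal"
            )
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "raw_reads", reads)

    @property
    def pct_activity(self) -> np.ndarray:
        return normalize_activity(
            self.raw_reads,
            self.pos_control_median,
            self.dmso_median,
            self.assay_mode,
        )


@dataclass
class CurveFit:
    """Four-parameter Hill fit plus curve class/rank once classified.

    ``ac50`` is molar; ``efficacy`` and ``baseline`` are in % activity.
    ``converged`` is False when no optimizer start produced a usable fit;
    downstream such curves are treated as inactive unless they qualify as
    single-point (class 3) activity.
    """

    ac50: float
    efficacy: float
    hill_slope: float
    baseline: float
    r2: float
    converged: bool = True
    curve_class: str | None = None
    curve_rank: int | None = None
    direction: int | None = None


@dataclass(frozen=True)
class ReproCall:
    compound_id: str
    replicate_ranks: tuple[int, int, int]
    call: Literal["active_match", "inactive_match", "inconclusive", "mismatch"]


@dataclass(frozen=True)
class AssayRepro:
    """Per-assay reproducibility summary over the triplicate screen."""

    pct_active_match: float
    pct_inactive_match: float
    pct_inconclusive: float
    pct_mismatch: float
    score: float
    mean_ac50_fold: float = float("nan")

    @property
    def grade(self) -> str:
        return score_grade(self.score)


def normalize_activity(
    raw_read,
    v_pos: float,
    v_dmso: float,
    mode: AssayMode = "agonist",
):
    """Normalize raw signal to % activity against in-plate controls.

    % activity = 100 * (V_compound - V_DMSO) / (V_pos - V_DMSO).  In
    antagonist mode the scale is shifted by -100 so DMSO maps to -100% and
    the positive control to 0% (activity is read as loss of signal).
    """
    if v_pos == v_dmso:
        raise DegenerateControlsError("v_pos == v_dmso: cannot normalize")
    pct = 100.0 * (np.asarray(raw_read, dtype=float) - v_dmso) / (v_pos - v_dmso)
    if mode == "antagonist":
        pct = pct - 100.0
    if np.ndim(raw_read) == 0:
        return float(pct)
    return pct


def correct_plate_pattern(
    plate: np.ndarray, control_plates: Sequence[np.ndarray]
) -> np.ndarray:
    """Subtract per-well background interpolated from bracketing DMSO plates.

    The background of each well is the mean of the first and last
    compound-free control plate (the plates bracketing the compound stack);
    a single control plate is its own bracket.
    """
    if len(control_plates) == 0:
        raise ValueError("at least one compound-free control plate is required")
    plate = np.asarray(plate, dtype=float)
    first = np.asarray(control_plates[0], dtype=float)
    last = np.asarray(control_plates[-1], dtype=float)
    if first.shape != plate.shape or last.shape != plate.shape:
        raise ValueError("control plates must share the plate's geometry")
    return plate - (first + last) / 2.0


def _hill(logc: np.ndarray, log_ac50: float, slope: float, baseline: float,
          efficacy: float) -> np.ndarray:
    return baseline + (efficacy - baseline) / (
        1.0 + 10.0 ** ((log_ac50 - logc) * slope)
    )


def fit_hill(concentrations, responses) -> CurveFit:
    """Least-squares four-parameter Hill fit in log10-concentration space.

    Multi-start over a fixed grid of initial AC50s spanning the tested
    range; AC50 is constrained to [min conc / 10, max conc * 10].  Among
    equal-r2 fits the one with the smaller |efficacy| wins (conservative).
    Constant response vectors are returned unconverged with efficacy 0.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.size < 4:
        raise ValueError("at least 4 titration points are required")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    logc = np.log10(conc)
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    if ss_tot == 0.0:
        return CurveFit(
            ac50=float("nan"), efficacy=0.0, hill_slope=float("nan"),
            baseline=float(resp[0]), r2=0.0, converged=False,
        )

    lo, hi = logc[0] - 1.0, logc[-1] + 1.0
    bounds = (
        np.array([lo, 0.2, -150.0, -250.0]),
        np.array([hi, 10.0, 150.0, 250.0]),
    )
    span = float(resp[-1] - resp[0])
    best: tuple[float, float, np.ndarray] | None = None  # (r2, |eff|, params)
    for start in np.linspace(logc[0], logc[-1], 6):
        x0 = np.array([start, 1.0, float(resp[0]), float(resp[0]) + span])
        x0 = np.clip(x0, bounds[0] + 1e-9, bounds[1] - 1e-9)
        try:
            sol = least_squares(
                lambda p: _hill(logc, *p) - resp, x0, bounds=bounds,
                method="trf", max_nfev=400,
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        r2 = 1.0 - float(np.sum(sol.fun**2)) / ss_tot
        eff = abs(sol.x[3] - 0.0)
        if best is None or r2 > best[0] + 1e-9 or (
            abs(r2 - best[0]) <= 1e-9 and eff < best[1]
        ):
            best = (r2, eff, sol.x)
    if best is None:
        return CurveFit(
            ac50=float("nan"), efficacy=0.0, hill_slope=float("nan"),
            baseline=float(resp.mean()), r2=0.0, converged=False,
        )
    r2, _, (log_ac50, slope, baseline, efficacy) = best
    return CurveFit(
        ac50=float(10.0**log_ac50),
        efficacy=float(efficacy),
        hill_slope=float(slope),
        baseline=float(baseline),
        r2=float(max(r2, 0.0)),
    )


def classify_and_rank(
    fit: CurveFit,
    responses,
    efficacy_threshold: float = 30.0,
    mode: AssayMode = "agonist",
    top_conc: float | None = None,
) -> CurveFit:
    """Assign a curve class and signed curve rank to a Hill fit.

    Classes: 1.1/1.2 complete curve (upper plateau inside the tested range),
    2.1/2.2 incomplete; x.1 high efficacy (|eff| >= 2*threshold), x.2 low;
    3 single-point activity at the top concentration; 4 inactive.  Activity
    for classes 1-2 requires |efficacy| >= threshold and r2 >= 0.5; class 3
    is exempt from the r2 gate.  Rank magnitudes 8/6/5/3/1/0 for classes
    1.1/2.1/1.2/2.2/3/4, +1 when AC50 < 1 uM (capped at 9), signed by the
    response direction.
    """
    resp = np.asarray(responses, dtype=float)
    # antagonist-mode responses live on [-100, 0]; activity direction is the
    # sign of the fitted span either way
    span = fit.efficacy - fit.baseline
    direction = 1 if span >= 0 else -1

    def _single_point() -> bool:
        if resp.size < 2:
            return False
        return abs(resp[-1]) >= efficacy_threshold and bool(
            np.all(np.abs(resp[:-1]) < efficacy_threshold)
        )

    active = (
        fit.converged
        and abs(fit.efficacy) >= efficacy_threshold
        and fit.r2 >= 0.5
    )
    if active:
        # completeness: fitted response at the top tested concentration
        # reaches >= 90% of the fitted span
        if top_conc is None:
            top_conc = _top_conc(fit)
        top = _hill(
            np.array([math.log10(top_conc)]),
            math.log10(fit.ac50),
            fit.hill_slope,
            fit.baseline,
            fit.efficacy,
        )[0]
        complete = abs(top - fit.baseline) >= 0.9 * abs(span)
        high = abs(fit.efficacy) >= 2.0 * efficacy_threshold
        cls = {
            (True, True): "1.1",
            (True, False): "1.2",
            (False, True): "2.1",
            (False, False): "2.2",
        }[(complete, high)]
    elif _single_point():
        cls = "3"
        direction = 1 if resp[-1] >= 0 else -1
    else:
        cls = "4"

    rank = _CLASS_RANK[cls]
    if (
        cls in ("1.1", "1.2", "2.1", "2.2")
        and fit.converged
        and fit.ac50 < POTENCY_BONUS_AC50
    ):
        rank = min(rank + 1, 9)
    signed = rank * direction if cls != "4" else 0
    return replace(
        fit, curve_class=cls, curve_rank=int(signed),
        direction=direction if cls != "4" else 0,
    )


# fit_titration records the top tested concentration on the fit so that
# classify_and_rank can judge curve completeness without the titration
_TOP_CONC_ATTR = "_top_conc"


def _top_conc(fit: CurveFit) -> float:
    top = getattr(fit, _TOP_CONC_ATTR, None)
    if top is None:
        # tested range unknown: judge completeness one decade above AC50
        return fit.ac50 * 10.0
    return top


def fit_titration(
    titration: RawTitration, efficacy_threshold: float = 30.0
) -> CurveFit:
    """Normalize, fit and classify a single raw titration."""
    resp = titration.pct_activity
    fit = fit_hill(titration.concentrations, resp)
    setattr(fit, _TOP_CONC_ATTR, float(titration.concentrations[-1]))
    return classify_and_rank(
        fit, resp, efficacy_threshold=efficacy_threshold,
        mode=titration.assay_mode,
        top_conc=float(titration.concentrations[-1]),
    )


def call_reproducibility(
    replicate_ranks: Sequence[int],
    active_cutoff: int = 3,
    compound_id: str = "",
) -> ReproCall:
    """Reduce three replicate curve ranks to a reproducibility call.

    A replicate is active when |rank| >= active_cutoff, inactive when
    rank == 0, marginal otherwise.  Mismatch: activity conflicts (active
    together with inactive, or actives of opposite sign); active match:
    >= 2 actives of a single sign and no inactive; inactive match: all
    three inactive; anything else is inconclusive.
    """
    ranks = tuple(int(r) for r in replicate_ranks)
    if len(ranks) != 3:
        raise ValueError("exactly 3 replicate ranks are required")
    if active_cutoff <= 0:
        raise ValueError("active_cutoff must be positive")
    active = [r for r in ranks if abs(r) >= active_cutoff]
    inactive = [r for r in ranks if r == 0]
    signs = {1 if r > 0 else -1 for r in active}
    if len(inactive) == 3:
        call = "inactive_match"
    elif (active and inactive) or len(signs) > 1:
        call = "mismatch"
    elif len(active) >= 2:
        call = "active_match"
    else:
        call = "inconclusive"
    return ReproCall(compound_id=compound_id, replicate_ranks=ranks, call=call)


def assay_repro_score(
    pct_active_match: float,
    pct_inactive_match: float,
    pct_inconclusive: float,
    pct_mismatch: float,
) -> float:
    """Assay reproducibility score = 2a + i - c - 2m over the four call rates."""
    if min(pct_active_match, pct_inactive_match,
           pct_inconclusive, pct_mismatch) < 0:
        raise ValueError("call percentages must be non-negative")
    return (
        2.0 * pct_active_match
        + pct_inactive_match
        - pct_inconclusive
        - 2.0 * pct_mismatch
    )


def score_grade(score: float) -> str:
    """Letter grade: A above 90, B for 80-90, C below."""
    if score > 90.0:
        return "A"
    if score >= 80.0:
        return "B"
    return "C"


def summarize_assay_repro(
    calls: Sequence[ReproCall], ac50_folds: Sequence[float] = ()
) -> AssayRepro:
    """Aggregate per-compound calls into assay-level rates and score."""
    if not calls:
        raise ValueError("no reproducibility calls to summarize")
    n = len(calls)
    pct = {
        kind: 100.0 * sum(c.call == kind for c in calls) / n
        for kind in ("active_match", "inactive_match", "inconclusive", "mismatch")
    }
    score = assay_repro_score(
        pct["active_match"], pct["inactive_match"],
        pct["inconclusive"], pct["mismatch"],
    )
    fold = float(np.mean(ac50_folds)) if len(ac50_folds) else float("nan")
    return AssayRepro(
        pct_active_match=pct["active_match"],
        pct_inactive_match=pct["inactive_match"],
        pct_inconclusive=pct["inconclusive"],
        pct_mismatch=pct["mismatch"],
        score=score,
        mean_ac50_fold=fold,
    )


def ac50_fold_change(ac50s: Sequence[float]) -> float:
    """Replicate AC50 spread as a fold: 10 ** sample SD of log10(AC50)."""
    vals = np.asarray(list(ac50s), dtype=float)
    if vals.size < 2:
        raise ValueError("at least 2 AC50 values are required")
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        raise ValueError("AC50 values must be positive and finite")
    return float(10.0 ** np.std(np.log10(vals), ddof=1))


def load_published_repro_table() -> pd.DataFrame:
    """Reproducibility call rates reported for the 30 Tox21 phase II assays.

    Columns: assay, pct_active_match, pct_inactive_match, pct_inconclusive,
    pct_mismatch, ac50_fold_change, published_score.
    """
    with resources.files("toxprofiler.data").joinpath(
        "assay_reproducibility.csv"
    ).open() as fh:
        return pd.read_csv(fh)
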