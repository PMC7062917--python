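"""Median-effect dose-response fitting and combination-index synergy analysis.

The median-effect equation fa/(1-fa) = (D/Dm)^m relates dose D to the
fraction affected fa; Dm is the dose giving fa = 0.5 (the GI50 when fa is
growth inhibition) and m the sigmoidicity slope.  Fitting is ordinary
least squares of log10(fa/(1-fa)) on log10(D).  For a combination of
doses (d1, d2) producing fa, the combination index is

    CI = d1/Dx1(fa) + d2/Dx2(fa),

where Dx_i(fa) is the single-agent dose producing fa; CI < 1 indicates
synergy, CI = 1 additivity, CI > 1 antagonism.  The optional third
(non-exclusive) term d1*d2/(Dx1*Dx2) is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import read_tsv

# log-odds diverge at 0/1; the clamp mirrors instrument precision
FA_MIN, FA_MAX = 0.005, 0.995

CI_TOL = 1e-9


@dataclass
class DoseResponse:
    """Observed (dose in uM, fraction affected) pairs for one agent."""

    agent: str
    observations: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for d, fa in self.observations:
            if d <= 0:
                raise ValueError(f"{self.agent}: doses must be positive")
            if not 0 < fa < 1:
                raise ValueError(f"{self.agent}: fa must lie in (0, 1) after clamping")


@dataclass
class MedianEffectFit:
    """(m, Dm, r2) of the log-linearised median-effect fit; fa(Dm) = 0.5."""

    agent: str
    m: float
    dm: float
    r2: float


@dataclass
class CIResult:
    d1: float
    d2: float
    fa: float
    ci: float

    @property
    def verdict(self) -> str:
        if self.ci < 1.0 - CI_TOL:
            return "synergy"
        if self.ci > 1.0 + CI_TOL:
            return "antagonism"
        return "additive"


def fa_from_fresh_weight(weight_treated: float, weight_control: float) -> float:
    """fa = 1 - treated/control fresh weight, clamped into [0.005, 0.995]."""
    if weight_control <= 0:
        raise ValueError("control fresh weight must be positive")
    if weight_treated <= 0:
        raise ValueError("treated fresh weight must be positive")
    return float(np.clip(1.0 - weight_treated / weight_control, FA_MIN, FA_MAX))


def fit_median_effect(dr: DoseResponse) -> MedianEffectFit:
    """OLS of log10(fa/(1-fa)) on log10(D): slope m, intercept -m*log10(Dm)."""
    doses = np.array([d for d, _ in dr.observations], dtype=float)
    fa = np.array([f for _, f in dr.observations], dtype=float)
    if len(np.unique(doses)) < 2:
        raise ValueError(f"{dr.agent}: need >= 2 distinct doses to fit")
    at_bound = (fa <= FA_MIN) | (fa >= FA_MAX)
    if at_bound.all():
        raise ValueError(f"{dr.agent}: all fa at a clamp bound; no dose-response information")
    x = np.log10(doses)
    y = np.log10(fa / (1.0 - fa))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    if slope <= 0:
        raise ValueError(f"{dr.agent}: non-positive median-effect slope; data not dose-responsive")
    dm = 10.0 ** (-intercept / slope)
    return MedianEffectFit(dr.agent, float(slope), float(dm), r2)


def dose_for_fa(fit: MedianEffectFit, fa: float) -> float:
    """Inverse median-effect relation: Dx = Dm * (fa/(1-fa))^(1/m)."""
    if not 0 < fa < 1:
        raise ValueError("fa must lie strictly between 0 and 1")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def combination_index(
    d1: float, d2: float, fa_combo: float,
    fit1: MedianEffectFit, fit2: MedianEffectFit,
    exclusive: bool = True,
) -> CIResult:
    """Two-term (mutually exclusive) combination index at the observed fa.

    ``exclusive=False`` adds the non-exclusive cross term d1*d2/(Dx1*Dx2).
    """
    dx1 = dose_for_fa(fit1, fa_combo)
    dx2 = dose_for_fa(fit2, fa_combo)
    ci = d1 / dx1 + d2 / dx2
    if not exclusive:
        ci += (d1 * d2) / (dx1 * dx2)
    return CIResult(d1, d2, fa_combo, float(ci))


def fa_ci_curve(combos, fit1: MedianEffectFit, fit2: MedianEffectFit, exclusive: bool = True) -> pd.DataFrame:
    """CI per (d1, d2, fa) combination, sorted ascending by fa (duplicates kept)."""
    if not combos:
        raise ValueError("need at least one combination")
    rows = []
    for d1, d2, fa in combos:
        res = combination_index(d1, d2, fa, fit1, fit2, exclusive=exclusive)
        rows.append({"d1_uM": d1, "d2_uM": d2, "fa": fa, "ci": res.ci, "verdict": res.verdict})
    return pd.DataFrame(rows).sort_values("fa", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# growth-table ingestion
# ---------------------------------------------------------------------------

GROWTH_COLUMNS = ["agent", "dose_uM", "replicate", "fresh_weight_mg"]
COMBO_COLUMNS = ["agent1", "dose1_uM", "agent2", "dose2_uM", "replicate", "fresh_weight_mg"]


def dose_responses_from_growth(growth: pd.DataFrame, control_label: str = "DMSO") -> dict[str, DoseResponse]:
    """Mean fresh weight per (agent, dose) against the mean control weight.

    Replicate weights are averaged per dose before the Fa transform.
    """
    missing = [c for c in GROWTH_COLUMNS if c not in growth.columns]
    if missing:
        raise ValueError(f"growth table missing columns {missing}")
    ctrl = growth[growth["agent"] == control_label]
    if ctrl.empty:
        raise ValueError(f"no control rows (agent == {control_label!r}) in growth table")
    w_ctrl = float(ctrl["fresh_weight_mg"].mean())
    out: dict[str, DoseResponse] = {}
    treated = growth[growth["agent"] != control_label]
    for agent, grp in treated.groupby("agent", sort=True):
        obs = []
        for dose, dgrp in grp.groupby("dose_uM", sort=True):
            obs.append((float(dose), fa_from_fresh_weight(float(dgrp["fresh_weight_mg"].mean()), w_ctrl)))
        out[agent] = DoseResponse(agent, obs)
    return out


def combo_fa_from_growth(combo: pd.DataFrame, control_weight_mg: float) -> pd.DataFrame:
    """Mean fresh weight per combination dose pair, transformed to fa."""
    missing = [c for c in COMBO_COLUMNS if c not in combo.columns]
    if missing:
        raise ValueError(f"combination table missing columns {missing}")
    rows = []
    keys = ["agent1", "dose1_uM", "agent2", "dose2_uM"]
    for key, grp in combo.groupby(keys, sort=True):
        fa = fa_from_fresh_weight(float(grp["fresh_weight_mg"].mean()), control_weight_mg)
        rows.append(dict(zip(keys, key)) | {"fa": fa})
    return pd.DataFrame(rows)


def read_growth_table(path) -> pd.DataFrame:
    return read_tsv(path)


def read_combo_table(path) -> pd.DataFrame:
    return read_tsv(path)
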