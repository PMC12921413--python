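"""Group-interaction harmonic (cosinor) model and rhythm-disruption calls.

For a metabolite measured in two groups over the circadian cycle, the model

    y = b0 + bg*g + (a0 + a1*g)*cos(w*t) + (b0s + b1s*g)*sin(w*t),
    g in {0 = LD, 1 = LL},  w = 2*pi/period

is fitted by least squares.  Per-group amplitude A = sqrt(a^2 + b^2) and
acrophase (peak time in ZT hours) follow from the group-specific (a, b)
pair; a joint 2-df F-test of the interaction terms (a1, b1) calls a rhythm
disruption.  Phase differences are reported wrapped to (-period/2, period/2]
with positive values meaning the LL peak occurs later (a phase delay).

Each sample is an independent animal, so a fixed-effects least-squares fit
of the stated formula is the default; there are no repeated measures that
would support a richer random-effects structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import AnalysisConfig, MetaboliteTable

COEF_NAMES = ("intercept", "group", "cos", "sin", "group:cos", "group:sin")


def wrap_phase(delta: float, period: float = 24.0) -> float:
    """Wrap a phase difference into (-period/2, period/2]."""
    d = float(delta) % period
    if d > period / 2:
        d -= period
    return d


@dataclass
class HarmonicFit:
    beta: np.ndarray            # coefficients in COEF_NAMES order
    cov: np.ndarray             # coefficient covariance (sigma2 * (X'X)^-1)
    sigma2: float
    df_resid: int
    period: float
    degenerate: bool = False    # zero residual variance (exact-fit case)

    def coef(self, name: str) -> float:
        return float(self.beta[COEF_NAMES.index(name)])


@dataclass
class RhythmParams:
    group: str
    mesor: float
    amplitude: float
    acrophase: float            # NaN when amplitude is 0
    flag: str = ""


@dataclass
class DisruptionResult:
    metabolite_id: str
    delta_phase: float          # hours, (-period/2, period/2], + = LL delayed
    amp_change_pct: float
    interaction_p: float
    disrupted: bool
    amplitude_ld: float
    amplitude_ll: float
    acrophase_ld: float
    acrophase_ll: float
    flag: str = ""


def _design_matrix(timepoints: np.ndarray, g: np.ndarray, period: float) -> np.ndarray:
    w = 2 * np.pi / period
    c, s = np.cos(w * timepoints), np.sin(w * timepoints)
    return np.column_stack([np.ones_like(c), g, c, s, g * c, g * s])


def fit_group_harmonic(values, timepoints, groups, period: float = 24.0) -> HarmonicFit:
    """Least-squares fit of the two-group harmonic interaction model.

    ``groups`` may be "LD"/"LL" labels or a 0/1 indicator. Requires both
    groups, >= 3 distinct timepoints per group, a full-rank design and at
    least one residual degree of freedom.
    """
    y = np.asarray(values, float)
    t = np.asarray(timepoints, float)
    garr = np.asarray(groups)
    if garr.dtype.kind in "USO":
        levels = sorted(set(garr))
        if len(levels) != 2:
            raise ValueError(f"need exactly two groups, got {levels}")
        g = (garr == levels[-1]).astype(float)  # LD=0, LL=1 under sorted order
    else:
        g = garr.astype(float)
        if set(np.unique(g)) - {0.0, 1.0}:
            raise ValueError("numeric group indicator must be 0/1")
        if np.unique(g).size != 2:
            raise ValueError("both groups must be present")
    for gi in (0.0, 1.0):
        if np.unique(t[g == gi]).size < 3:
            raise ValueError("each group needs >= 3 distinct timepoints")

    X = _design_matrix(t, g, period)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [COEF_NAMES[i] for i in range(X.shape[1])
               if abs(R[i, i]) < 1e-8 * abs(R).max()]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    df_resid = y.size - X.shape[1]
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    scale = max(float(y @ y), 1.0)
    degenerate = ss_res <= 1e-24 * scale
    sigma2 = ss_res / df_resid
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return HarmonicFit(beta=beta, cov=cov, sigma2=sigma2, df_resid=df_resid,
                       period=period, degenerate=degenerate)


def derive_rhythm_params(fit: HarmonicFit, group: str) -> RhythmParams:
    """Mesor, amplitude and acrophase (ZT hours) for one group.

    The fitted a*cos(wt) + b*sin(wt) equals A*cos(w*(t - phi)) with
    A = hypot(a, b) and phi = atan2(b, a)/w, so the acrophase is the peak
    time of the fitted cosine expressed on the ZT clock.
    """
    ll = group == "LL"
    a = fit.coef("cos") + (fit.coef("group:cos") if ll else 0.0)
    b = fit.coef("sin") + (fit.coef("group:sin") if ll else 0.0)
    mesor = fit.coef("intercept") + (fit.coef("group") if ll else 0.0)
    amp = math.hypot(a, b)
    if amp == 0.0:
        return RhythmParams(group, mesor, 0.0, float("nan"), flag="zero_amplitude")
    acro = (math.atan2(b, a) * fit.period / (2 * math.pi)) % fit.period
    if acro >= fit.period:  # float wrap of a tiny negative angle
        acro -= fit.period
    return RhythmParams(group, mesor, amp, acro)


def interaction_test(fit: HarmonicFit) -> tuple[float, str]:
    """Joint F-test of H0: both interaction coefficients are zero.

    Returns (p, flag); degenerate (exact-fit) residual variance yields
    p = NaN with flag "degenerate" rather than a spurious claim.
    """
    if fit.degenerate or fit.sigma2 <= 0:
        return float("nan"), "degenerate"
    idx = [COEF_NAMES.index("group:cos"), COEF_NAMES.index("group:sin")]
    b = fit.beta[idx]
    V = fit.cov[np.ix_(idx, idx)]
    F = float(b @ np.linalg.solve(V, b)) / 2.0
    return float(stats.f.sf(F, 2, fit.df_resid)), ""


def phase_difference(acro_ll: float, acro_ld: float, period: float = 24.0) -> float:
    """(LL acrophase - LD acrophase) wrapped to (-period/2, period/2];
    positive = LL peaks later (phase delay)."""
    if not (np.isfinite(acro_ll) and np.isfinite(acro_ld)):
        return float("nan")
    return wrap_phase(acro_ll - acro_ld, period)


def amplitude_change_pct(amp_ll: float, amp_ld: float) -> float:
    """Signed percent change (LL - LD)/LD * 100; NaN when LD amplitude is 0."""
    if not np.isfinite(amp_ld) or amp_ld <= 0:
        return float("nan")
    return 100.0 * (amp_ll - amp_ld) / amp_ld


def classify_peak_epoch(acrophase: float, period: float = 24.0) -> str:
    """"night" iff the acrophase falls in [period/2, period) -- the dark
    phase under the 12:12 convention with lights-on at ZT0."""
    if not np.isfinite(acrophase):
        raise ValueError("acrophase must be finite")
    return "night" if (acrophase % period) >= period / 2 else "day"


def nocturnal_fraction(acrophases, period: float = 24.0) -> float:
    a = np.asarray(acrophases, float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return float("nan")
    return float(np.mean((a % period) >= period / 2))


def compare_rhythms(table: MetaboliteTable, rhythmic_ids,
                    config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Disruption calls for a set of (LD-rhythmic) metabolites.

    Per-metabolite failures are recorded in the flag column and the run
    continues. Returns one row per metabolite with fitted per-group
    amplitude/acrophase, wrapped phase difference, amplitude change % and
    the interaction p-value; disrupted <=> interaction_p < p_threshold.
    """
    config = config or AnalysisConfig()
    t = table.meta["zt"].to_numpy(float)
    g = table.meta["group"].to_numpy()
    rows = []
    for mid in rhythmic_ids:
        try:
            y = table.abundance.loc[mid].to_numpy(float)
            fit = fit_group_harmonic(y, t, g, period=config.period)
            ld = derive_rhythm_params(fit, "LD")
            ll = derive_rhythm_params(fit, "LL")
            p, flag = interaction_test(fit)
            res = DisruptionResult(
                metabolite_id=mid,
                delta_phase=phase_difference(ll.acrophase, ld.acrophase, config.period),
                amp_change_pct=amplitude_change_pct(ll.amplitude, ld.amplitude),
                interaction_p=p,
                disrupted=bool(np.isfinite(p) and p < config.p_threshold),
                amplitude_ld=ld.amplitude, amplitude_ll=ll.amplitude,
                acrophase_ld=ld.acrophase, acrophase_ll=ll.acrophase,
                flag="; ".join(f for f in (flag, ld.flag, ll.flag) if f))
        except Exception as exc:  # record and continue
            res = DisruptionResult(mid, float("nan"), float("nan"), float("nan"),
                                   False, float("nan"), float("nan"),
                                   float("nan"), float("nan"), flag=f"error: {exc}")
        rows.append(res)
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("metabolite_id")
    return df
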