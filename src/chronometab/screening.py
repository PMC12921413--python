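"""Differential screening: routed two-group statistics, fold-change and
VIP-based screens, PCA/PLS-DA, permutation validation, Venn regions and QC.

Normality routing follows the convention of reporting Shapiro-Wilk-gated
statistics: when both groups pass Shapiro-Wilk at alpha the comparison is a
pooled-variance Student t-test with Cohen's d; otherwise a Mann-Whitney U
with the rank-biserial correlation r = Z/sqrt(N).  Z uses the tie-corrected
normal approximation without a continuity correction (the convention that
reproduces published r values from U and group sizes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold, LeaveOneOut

from .dataio import AnalysisConfig, MetaboliteTable


@dataclass
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass
class TestResult:
    statistic_name: str     # "t" | "U" | "W"
    statistic: float
    df: float | None
    p: float
    effect_name: str        # "cohens_d" | "rank_biserial_r"
    effect: float
    route: str              # "parametric" | "nonparametric"
    flag: str = ""


def normality_route(x, y, alpha: float = 0.05) -> tuple[str, str]:
    """Choose the test family: parametric iff both groups pass Shapiro-Wilk.

    Groups with n < 3 cannot be tested for normality; they are routed
    nonparametric with a warning flag.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if min(x.size, y.size) < 3:
        return "nonparametric", "n<3: normality untestable"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns for near-constant input
        try:
            px = stats.shapiro(x).pvalue
            py = stats.shapiro(y).pvalue
        except ValueError:
            return "nonparametric", "shapiro failed (constant input)"
    route = "parametric" if (px > alpha and py > alpha) else "nonparametric"
    return route, ""


def _as_summary(g) -> GroupSummary:
    if isinstance(g, GroupSummary):
        return g
    arr = np.asarray(g, float)
    if arr.ndim == 1 and arr.size == 3 and arr[2] == int(arr[2]) and arr[2] >= 2 \
            and not isinstance(g, np.ndarray):
        # a (mean, sd, n) triple passed as tuple/list
        return GroupSummary(float(arr[0]), float(arr[1]), int(arr[2]))
    return GroupSummary(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size))


def ttest_with_d(group1, group2) -> TestResult:
    """Pooled-variance two-sample t with Cohen's d.

    Accepts raw value arrays or printed summaries: a GroupSummary or a
    (mean, sd, n) tuple.  d = (mean1 - mean2)/pooled SD; df = n1 + n2 - 2.
    The summary path and the raw path agree exactly when summaries come from
    the same raw data.
    """
    s1, s2 = _as_summary(group1), _as_summary(group2)
    df = s1.n + s2.n - 2
    pooled_var = ((s1.n - 1) * s1.sd ** 2 + (s2.n - 1) * s2.sd ** 2) / df
    if pooled_var <= 0:
        return TestResult("t", float("nan"), df, float("nan"), "cohens_d",
                          float("nan"), "parametric", flag="zero pooled SD")
    sp = math.sqrt(pooled_var)
    se = sp * math.sqrt(1 / s1.n + 1 / s2.n)
    t = (s1.mean - s2.mean) / se
    p = 2 * stats.t.sf(abs(t), df)
    d = (s1.mean - s2.mean) / sp
    return TestResult("t", t, df, float(p), "cohens_d", d, "parametric")


def rank_biserial_from_u(U: float, n1: int, n2: int,
                         tie_term: float = 0.0) -> tuple[float, float, float]:
    """(Z, two-sided p, r) from a U statistic and group sizes.

    Z = (U - n1*n2/2)/sigma_U with the tie-corrected variance
    sigma_U^2 = n1*n2/12 * (n+1 - tie_term/(n*(n-1))), tie_term =
    sum(t^3 - t); r = Z/sqrt(n1+n2).  No continuity correction.
    """
    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0, 1.0, 0.0
    z = (U - n1 * n2 / 2.0) / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return z, float(p), z / math.sqrt(n)


def rank_biserial_simple(U: float, n1: int, n2: int) -> float:
    """The 1 - 2U/(n1*n2) form of the rank-biserial correlation."""
    return 1.0 - 2.0 * U / (n1 * n2)


def mannwhitney_with_r(x, y, exact_limit: int = 12) -> TestResult:
    """Mann-Whitney U with midrank ties and the r = Z/sqrt(N) effect size.

    U is the statistic of the first sample (pairs where x exceeds y, ties
    counted half).  p is exact (distribution-free enumeration) when
    n1 + n2 <= exact_limit and no ties are present, otherwise the
    tie-corrected normal approximation.  Fully tied input yields
    U = n1*n2/2, p = 1, r = 0.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    _, counts = np.unique(pooled, return_counts=True)
    has_ties = (counts > 1).any()
    tie_term = float(np.sum(counts ** 3 - counts))
    if np.unique(pooled).size == 1:
        return TestResult("U", n1 * n2 / 2.0, None, 1.0, "rank_biserial_r",
                          0.0, "nonparametric", flag="all values tied")
    z, p_norm, r = rank_biserial_from_u(u1, n1, n2, tie_term)
    if not has_ties and n1 + n2 <= exact_limit:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue)
    else:
        p = p_norm
    return TestResult("U", u1, None, p, "rank_biserial_r", r, "nonparametric")


def routed_test(x, y, alpha: float = 0.05) -> TestResult:
    """Normality-routed comparison of two raw samples."""
    route, flag = normality_route(x, y, alpha)
    res = ttest_with_d(np.asarray(x, float), np.asarray(y, float)) \
        if route == "parametric" else mannwhitney_with_r(x, y)
    res.route = route
    if flag:
        res.flag = "; ".join(f for f in (res.flag, flag) if f)
    return res


def relative_expression_ddct(ct_target: float, ct_ref: float,
                             calibrator_delta: float) -> float:
    """Relative qPCR expression 2^-((Ct_target - Ct_ref) - calibrator_delta)."""
    return float(2.0 ** -((ct_target - ct_ref) - calibrator_delta))


# ---------------------------------------------------------------------------
# table-level screens

def fold_change_screen(table: MetaboliteTable,
                       config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Global differential screen over all pooled samples.

    FC = mean(LL)/mean(LD); a metabolite passes iff max(FC, 1/FC) exceeds
    the FC threshold (two-sided volcano criterion) AND the normality-routed
    univariate p is below p_threshold.
    """
    config = config or AnalysisConfig()
    if set(table.groups) != {"LD", "LL"}:
        raise ValueError("global screen needs both LD and LL groups")
    ld_cols = table.meta.index[table.meta["group"] == "LD"]
    ll_cols = table.meta.index[table.meta["group"] == "LL"]
    rows = []
    for mid in table.metabolite_ids:
        x = table.abundance.loc[mid, ll_cols].to_numpy(float)  # LL
        y = table.abundance.loc[mid, ld_cols].to_numpy(float)  # LD
        tx, ty = (np.log2(x + 1e-12), np.log2(y + 1e-12)) \
            if config.log_transform else (x, y)
        res = routed_test(tx, ty, config.p_threshold)
        m_ll, m_ld = float(np.mean(x)), float(np.mean(y))
        if m_ll <= 0 or m_ld <= 0:
            rows.append((mid, float("nan"), float("nan"), res.p, res.route,
                         False, "non-positive group mean"))
            continue
        fc = m_ll / m_ld
        passes = max(fc, 1 / fc) > config.fc_threshold and res.p < config.p_threshold
        rows.append((mid, fc, math.log2(fc), res.p, res.route, passes, res.flag))
    return pd.DataFrame(rows, columns=["metabolite_id", "fc", "log2fc", "p_uni",
                                       "route", "passes_global", "flag"]
                        ).set_index("metabolite_id")


def _preprocess(X: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray]:
    """Center (and optionally autoscale) columns; returns (Xp, keep_mask)."""
    X = np.asarray(X, float)
    keep = np.ones(X.shape[1], bool)
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} constant variable(s) "
                          "under unit-variance scaling")
        Xc = Xc[:, keep] / sd[keep]
    return Xc, keep


def pca_scores(X, n_components: int = 2, scale: bool = True
               ) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores and explained-variance fractions (samples x variables in)."""
    Xp, _ = _preprocess(X, scale)
    n_components = min(n_components, Xp.shape[0] - 1, Xp.shape[1])
    if n_components < 1:
        raise ValueError("need at least 2 samples")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xp)
    return scores, pca.explained_variance_ratio_


@dataclass
class PlsModel:
    n_components: int
    weights: np.ndarray      # (p, a), unit-norm columns
    x_scores: np.ndarray     # (n, a)
    y_loadings: np.ndarray   # (a,)
    ssy: np.ndarray          # Y-variance explained per component
    r2y: float
    q2: float
    classes: tuple
    keep_mask: np.ndarray    # variables retained after preprocessing
    n_features_in: int


def _encode_labels(labels) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) != 2:
        raise ValueError(f"PLS-DA needs exactly two classes, got {classes}")
    y = np.where(labels == classes[1], 1.0, -1.0)
    if min((y == 1).sum(), (y == -1).sum()) < 2:
        raise ValueError("each class needs >= 2 samples")
    return y, classes


def plsda_fit(X, labels, n_components: int = 2, cv_folds: int | None = None,
              scale: bool = True, compute_q2: bool = True) -> PlsModel:
    """PLS-DA of a samples x variables matrix against a two-class label.

    Data are centred (and autoscaled by default); y is the +/-1 class
    indicator.  Reports R2Y and a cross-validated Q2 (leave-one-out up to 24
    samples, otherwise 7-fold), with preprocessing re-estimated inside each
    training fold.  n_components is truncated to the identifiable maximum
    with a warning.
    """
    X = np.asarray(X, float)
    y, classes = _encode_labels(labels)
    Xp, keep = _preprocess(X, scale)
    max_comp = min(Xp.shape[0] - 1, Xp.shape[1])
    if n_components > max_comp:
        warnings.warn(f"n_components truncated from {n_components} to {max_comp}")
        n_components = max_comp
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xp, y)
    t = pls.x_scores_
    q = pls.y_loadings_.ravel()
    ssy = (q ** 2) * np.sum(t ** 2, axis=0)
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    resid = y - pls.predict(Xp).ravel()
    r2y = 1.0 - float(resid @ resid) / ss_tot

    q2 = float("nan")
    if compute_q2:
        if cv_folds is None:
            splitter = LeaveOneOut() if X.shape[0] <= 24 else KFold(
                n_splits=7, shuffle=True, random_state=0)
        else:
            splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=0)
        press = 0.0
        for tr, te in splitter.split(X):
            Xtr, keep_tr = _preprocess(X[tr], scale)
            mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0, ddof=1)
            Xte = (X[te] - mu)
            if scale:
                Xte = Xte[:, keep_tr] / sd[keep_tr]
            k = min(n_components, len(tr) - 1, Xtr.shape[1])
            m = PLSRegression(n_components=k, scale=False).fit(Xtr, y[tr])
            press += float(np.sum((y[te] - m.predict(Xte).ravel()) ** 2))
        q2 = 1.0 - press / ss_tot

    return PlsModel(n_components=n_components, weights=pls.x_weights_,
                    x_scores=t, y_loadings=q, ssy=ssy, r2y=r2y, q2=q2,
                    classes=classes, keep_mask=keep, n_features_in=X.shape[1])


def vip_scores(model: PlsModel) -> np.ndarray:
    """Variable importance in projection for every input variable.

    VIP_j = sqrt(p * sum_a SSY_a * w_ja^2 / sum_a SSY_a) with unit-norm
    weight vectors, so sum_j VIP_j^2 = p.  Variables dropped during scaling
    get VIP 0.
    """
    total = float(model.ssy.sum())
    if total <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    W = model.weights / np.linalg.norm(model.weights, axis=0, keepdims=True)
    p = W.shape[0]
    vip_kept = np.sqrt(p * (W ** 2 @ model.ssy) / total)
    vip = np.zeros(model.n_features_in)
    vip[model.keep_mask] = vip_kept
    return vip


def permutation_validate(X, labels, n_perm: int = 1000, seed: int = 0,
                         n_components: int = 2, statistic: str = "r2y",
                         scale: bool = True) -> tuple[float, float, np.ndarray]:
    """Permutation test of PLS-DA model reliability.

    Refits the model on label permutations and reports
    p = (1 + #{perm stat >= observed}) / (1 + n_perm) for the chosen
    statistic ("r2y" or "q2").  Returns (p, observed, permuted array).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = np.asarray(labels)
    if len(set(labels.tolist())) != 2:
        raise ValueError("degenerate labels")
    def stat(lab):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = plsda_fit(X, lab, n_components=n_components, scale=scale,
                          compute_q2=(statistic == "q2"))
        return m.r2y if statistic == "r2y" else m.q2
    observed = stat(labels)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for b in range(n_perm):
        perms[b] = stat(rng.permutation(labels))
    p = (1 + int(np.sum(perms >= observed))) / (1 + n_perm)
    return float(p), float(observed), perms


def timepoint_screen(table: MetaboliteTable, zt: float,
                     config: AnalysisConfig | None = None) -> pd.DataFrame | None:
    """Timepoint-specific screen: PLS-DA VIP plus routed univariate p at one ZT.

    passes_timepoint <=> VIP > vip_threshold AND p < p_threshold.  Returns
    None (with a warning) when the timepoint is absent or a group has fewer
    than 2 samples there.
    """
    config = config or AnalysisConfig()
    sub = table.subset(zt=zt)
    if sub.meta.empty:
        warnings.warn(f"timepoint ZT{zt:g} absent; skipped")
        return None
    counts = sub.meta["group"].value_counts()
    if set(counts.index) != {"LD", "LL"} or counts.min() < 2:
        warnings.warn(f"timepoint ZT{zt:g} lacks >=2 samples per group; skipped")
        return None
    X = sub.abundance.to_numpy(float).T  # samples x metabolites
    if config.log_transform:
        X = np.log2(X + 1e-12)
    labels = sub.meta["group"].to_numpy()
    n_comp = min(2, X.shape[0] - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = plsda_fit(X, labels, n_components=n_comp, scale=config.autoscale)
        vip = vip_scores(model)
    ld_cols = sub.meta.index[labels == "LD"]
    ll_cols = sub.meta.index[labels == "LL"]
    rows = []
    for j, mid in enumerate(sub.metabolite_ids):
        x = sub.abundance.loc[mid, ll_cols].to_numpy(float)
        y = sub.abundance.loc[mid, ld_cols].to_numpy(float)
        res = routed_test(x, y, config.p_threshold)
        m_ll, m_ld = float(np.mean(x)), float(np.mean(y))
        fc = m_ll / m_ld if m_ld > 0 and m_ll > 0 else float("nan")
        passes = bool(vip[j] > config.vip_threshold and res.p < config.p_threshold)
        rows.append((mid, zt, fc, res.p, res.route, float(vip[j]), passes))
    return pd.DataFrame(rows, columns=["metabolite_id", "zt", "fc", "p_uni",
                                       "route", "vip", "passes_timepoint"]
                        ).set_index("metabolite_id")


def timepoint_union(screens: dict[float, pd.DataFrame]) -> set[str]:
    """Union of timepoint-specific hits across ZTs."""
    hits: set[str] = set()
    for df in screens.values():
        if df is not None:
            hits |= set(df.index[df["passes_timepoint"]])
    return hits


def venn_counts(sets) -> dict[tuple[int, ...], int]:
    """Exact exclusive-region counts for up to ~6 sets.

    Keys are membership tuples, e.g. (1, 0, 1, 0) = items in sets 1 and 3
    only; only the 2^k - 1 non-empty-membership regions are returned.
    """
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    universe = set().union(*sets)
    counts: dict[tuple[int, ...], int] = {}
    for item in universe:
        key = tuple(int(item in s) for s in sets)
        counts[key] = counts.get(key, 0) + 1
    k = len(sets)
    for mask in range(1, 2 ** k):
        key = tuple((mask >> i) & 1 for i in range(k))
        counts.setdefault(key, 0)
    return counts


def shared_by_exactly(counts: dict[tuple[int, ...], int], m: int) -> int:
    """Number of items belonging to exactly m of the sets."""
    return sum(c for key, c in counts.items() if sum(key) == m)


def qc_correlation(qc) -> tuple[pd.DataFrame, float]:
    """Pairwise Pearson r between QC sample columns.

    Returns the symmetric correlation matrix (unit diagonal; NaN rows for
    zero-variance samples, flagged via warning) and the minimum off-diagonal
    r among well-defined pairs.
    """
    qc = pd.DataFrame(qc)
    if qc.shape[1] < 2:
        raise ValueError("need >= 2 QC samples")
    sd = qc.std(axis=0, ddof=1)
    if (sd == 0).any():
        warnings.warn(f"zero-variance QC sample(s): {list(qc.columns[sd == 0])}")
    corr = qc.corr()
    off = corr.to_numpy()[~np.eye(corr.shape[0], dtype=bool)]
    off = off[np.isfinite(off)]
    return corr, float(off.min()) if off.size else float("nan")
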