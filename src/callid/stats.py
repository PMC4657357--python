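"""Individuality statistics for per-call acoustic descriptors.

The central quantity is the potential for individual coding (PIC) of a
parameter: the coefficient of variation across all calls (CVb) divided by
the mean of the within-individual coefficients of variation (CVw), each
CVw carrying the small-sample correction ``(1 + 1/(4n))``::

    CVb = 100 * SD / mean          (over the pooled sample)
    CVw = 100 * (SD / mean) * (1 + 1/(4 n))   (per individual)
    PIC = CVb / mean(CVw)

PIC > 1 marks a parameter that varies more between individuals than within
one — a candidate identity cue.

Around PIC sit the screening and classification steps of the standard
workflow: univariate group tests (Kruskal–Wallis for temporal, one-way
ANOVA for spectral parameters), variance-inflation-factor screening for
multicollinearity, robust-Mahalanobis outlier flagging, covariance
diagnostics (Box's M; Mardia's multivariate normality), random class-size
balancing, quadratic discriminant analysis scored by jack-knife
leave-one-out cross-validation, and forward stepwise feature ranking.

Sample standard deviations use the n−1 denominator throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PicTable",
    "DfaResult",
    "ScreeningReport",
    "StepwiseResult",
    "cv_between",
    "cv_within",
    "pic",
    "pic_table",
    "kruskal_wallis",
    "one_way_anova",
    "vif_screen",
    "robust_outliers",
    "balance_classes",
    "qda_loocv",
    "stepwise_select",
    "covariance_diagnostics",
]


# ---------------------------------------------------------------------------
# coefficients of variation and PIC


def cv_between(values) -> float:
    """Between-individual CV (%): ``100 × SD / mean`` over the pooled sample."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CVb needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CVb is undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def cv_within(values) -> float:
    """Within-individual CV (%) with the small-sample correction.

    ``100 × (SD/mean) × (1 + 1/(4n))`` for one individual's ``n`` values.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("CVw needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CVw is undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean * (1.0 + 1.0 / (4.0 * n)))


def pic(cvb: float, cvw_per_individual) -> float:
    """PIC ratio: ``CVb / mean(CVw)``; > 1 suggests an identity cue."""
    cvw = np.asarray(cvw_per_individual, dtype=float)
    mean_cvw = cvw.mean()
    if mean_cvw <= 0:
        raise ValueError("PIC is undefined for non-positive mean CVw")
    return float(cvb / mean_cvw)


@dataclass
class PicTable:
    """Per-parameter CVb, per-individual CVw, mean CVw and PIC."""

    table: pd.DataFrame  # index = parameter, columns = CVb, CVw_<id>..., mean_CVw, PIC

    def rounded(self) -> pd.DataFrame:
        """Report layout: CVs and PIC rounded to 2 decimals."""
        return self.table.round(2)

    def to_csv(self, path) -> None:
        self.rounded().to_csv(path)


def pic_table(
    df: pd.DataFrame, parameters, label_col: str = "individual"
) -> PicTable:
    """Build the PIC table for several parameters from a per-call frame.

    Rows with a missing value for a parameter are dropped for that
    parameter only (short trains leave the block averages undefined).
    """
    labels = sorted(df[label_col].dropna().unique())
    rows = {}
    for param in parameters:
        sub = df[[label_col, param]].dropna()
        cvb = cv_between(sub[param].to_numpy())
        cvws = {
            lab: cv_within(sub.loc[sub[label_col] == lab, param].to_numpy())
            for lab in labels
        }
        mean_cvw = float(np.mean(list(cvws.values())))
        rows[param] = {
            "CVb": cvb,
            **{f"CVw_{lab}": v for lab, v in cvws.items()},
            "mean_CVw": mean_cvw,
            "PIC": cvb / mean_cvw,
        }
    return PicTable(table=pd.DataFrame.from_dict(rows, orient="index"))


# ---------------------------------------------------------------------------
# univariate group tests


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H test; returns ``(H, df, p)``."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("Kruskal-Wallis needs >= 2 non-empty groups")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; H statistic is 0", stacklevel=2)
        return 0.0, df, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), df, float(p)


def one_way_anova(groups) -> tuple[float, int, int, float]:
    """One-way ANOVA; returns ``(F, df1, df2, p)`` with df1=k−1, df2=N−k."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    if all(np.allclose(g, g[0]) for g in groups):
        warnings.warn("zero within-group variance; F is degenerate", stacklevel=2)
        return float("nan"), k - 1, n_total - k, float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*groups)
    return float(f), k - 1, n_total - k, float(p)


# ---------------------------------------------------------------------------
# screening


@dataclass
class ScreeningReport:
    vif: dict = field(default_factory=dict)  # final VIFs of retained features
    vif_initial: dict = field(default_factory=dict)
    removed: list = field(default_factory=list)  # removal order
    retained: list = field(default_factory=list)
    outlier_flags: np.ndarray | None = None
    outlier_distances: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)


def _vif_values(X: pd.DataFrame) -> dict:
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    exog = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, col in enumerate(X.columns):
            out[col] = float(variance_inflation_factor(exog, j + 1))
    return out


def vif_screen(X: pd.DataFrame, threshold: float = 20.0) -> ScreeningReport:
    """Iterative variance-inflation-factor screening.

    VIF_j = 1 / (1 − R²_j) from regressing feature j on the others; the
    feature with the largest VIF above ``threshold`` is removed, and VIFs
    are recomputed until all retained features fall below the threshold.
    Perfectly collinear features have infinite VIF and are removed first.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF screening needs >= 2 features")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("VIF screening needs more rows than features")
    report = ScreeningReport(vif_initial=_vif_values(X))
    work = X.copy()
    while work.shape[1] >= 2:
        vifs = _vif_values(work)
        worst = max(vifs, key=lambda c: (np.isinf(vifs[c]), vifs[c]))
        if not (np.isinf(vifs[worst]) or vifs[worst] > threshold):
            report.vif = vifs
            break
        report.removed.append(worst)
        work = work.drop(columns=[worst])
    else:
        report.vif = _vif_values(work) if work.shape[1] >= 2 else {}
    report.retained = list(work.columns)
    return report


def drop_degenerate_within(
    features: pd.DataFrame, labels, rel_tol: float = 1e-9
) -> list:
    """Features usable by per-class Gaussian models.

    Returns the columns whose within-class standard deviation is nonzero
    for every class.  A feature that is constant inside some class (e.g. a
    10 dB band edge pinned at the analysis-band limit for a wideband
    caller) makes that class's covariance singular and cannot enter QDA.
    """
    y = np.asarray(labels)
    keep = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        ok = True
        for c in np.unique(y):
            xc = x[y == c]
            scale = max(np.abs(xc).max(), 1.0)
            if xc.std(ddof=1) <= rel_tol * scale:
                ok = False
                break
        if ok:
            keep.append(col)
    return keep


def robust_outliers(
    X, quantile: float = 0.975, random_state: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Flag multivariate outliers by robust (MCD) Mahalanobis distance.

    Location and scatter come from the high-breakdown minimum covariance
    determinant estimate; rows whose squared robust distance exceeds the
    chi-square ``quantile`` at ``p`` degrees of freedom are flagged.  Flags
    are informational — rows are never removed here (dropping a point is an
    explicit, documented analyst decision).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= 2 * p:
        raise ValueError("robust outlier search needs n > 2p rows")
    from sklearn.covariance import MinCovDet

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mcd = MinCovDet(random_state=random_state).fit(X)
        if np.linalg.matrix_rank(mcd.covariance_) < p:
            raise np.linalg.LinAlgError
        d2 = mcd.mahalanobis(X)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ValueError(
            "singular robust scatter; screen collinear/constant features first"
        ) from exc
    cut = sps.chi2.ppf(quantile, df=p)
    return d2 > cut, d2


def balance_classes(
    df: pd.DataFrame, label_col: str, target_n: int, seed: int
) -> pd.DataFrame:
    """Randomly subsample classes above ``target_n`` down to it.

    Classes at or below the cap are untouched; sampling is without
    replacement and deterministic for a given seed.  Reduces the class-size
    disparity that would otherwise dominate proportional-prior QDA.
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    rng = np.random.default_rng(seed)
    parts = []
    for label in sorted(df[label_col].dropna().unique()):
        sub = df[df[label_col] == label]
        if len(sub) > target_n:
            idx = rng.choice(len(sub), size=target_n, replace=False)
            sub = sub.iloc[np.sort(idx)]
        parts.append(sub)
    return pd.concat(parts).sort_index()


# ---------------------------------------------------------------------------
# quadratic discriminant analysis with leave-one-out CV


@dataclass
class DfaResult:
    confusion: pd.DataFrame  # rows = true class, columns = predicted
    overall_rate_pct: float
    per_class_rate_pct: dict
    priors_used: dict
    features: list

    def to_json_dict(self) -> dict:
        return {
            "confusion": {
                str(k): {str(c): int(v) for c, v in row.items()}
                for k, row in self.confusion.to_dict(orient="index").items()
            },
            "overall_rate_pct": round(self.overall_rate_pct, 1),
            "per_class_rate_pct": {
                str(k): round(v, 1) for k, v in self.per_class_rate_pct.items()
            },
            "priors_used": {str(k): v for k, v in self.priors_used.items()},
            "features": list(self.features),
        }


class _QdaModel:
    """Per-class Gaussian classifier (class mean + class covariance)."""

    def __init__(self, X: np.ndarray, y: np.ndarray, priors: dict):
        self.classes = sorted(priors)
        self.priors = priors
        self.params = {}
        p = X.shape[1]
        for c in self.classes:
            Xc = X[y == c]
            if Xc.shape[0] <= p + 1:
                raise ValueError(
                    f"class {c!r} has too few rows ({Xc.shape[0]}) for a "
                    f"{p}-feature covariance"
                )
            mu = Xc.mean(axis=0)
            cov = np.cov(Xc, rowvar=False, ddof=1).reshape(p, p)
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise ValueError(f"singular covariance for class {c!r}")
            self.params[c] = (mu, np.linalg.inv(cov), logdet)

    def predict(self, x: np.ndarray):
        best, best_score = None, -np.inf
        for c in self.classes:
            mu, inv, logdet = self.params[c]
            d = x - mu
            score = np.log(self.priors[c]) - 0.5 * (logdet + d @ inv @ d)
            if score > best_score:
                best, best_score = c, score
        return best


def _resolve_priors(y: np.ndarray, priors) -> dict:
    classes = sorted(np.unique(y).tolist())
    if priors == "proportional":
        counts = {c: float(np.sum(y == c)) for c in classes}
        total = sum(counts.values())
        return {c: counts[c] / total for c in classes}
    if priors == "uniform":
        return {c: 1.0 / len(classes) for c in classes}
    if isinstance(priors, dict):
        total = sum(priors.values())
        return {c: priors[c] / total for c in classes}
    raise ValueError(f"unknown priors specification {priors!r}")


def qda_loocv(features, labels, priors="proportional") -> DfaResult:
    """Quadratic DFA scored by jack-knife leave-one-out cross-validation.

    For every call, per-class Gaussians (class mean and class covariance)
    are fit on all *other* calls and the held-out call is assigned to the
    class maximizing the prior-weighted log-density.  Priors default to
    class sample proportions ("equal sample size" priors); ``"uniform"``
    and explicit dicts are also accepted.  The overall correct-classification
    rate is the confusion-matrix trace over the total.
    """
    if isinstance(features, pd.DataFrame):
        feature_names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(labels)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) != len(y):
        raise ValueError("features and labels disagree in length")
    prior_map = _resolve_priors(y, priors)
    classes = sorted(prior_map)
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    idx = np.arange(len(y))
    for i in idx:
        mask = idx != i
        # priors follow the full-sample class sizes, as a fixed design choice
        model = _QdaModel(X[mask], y[mask], prior_map)
        pred = model.predict(X[i])
        conf.loc[y[i], pred] += 1
    total = conf.to_numpy().sum()
    correct = np.trace(conf.to_numpy())
    per_class = {
        c: 100.0 * conf.loc[c, c] / conf.loc[c].sum() for c in classes
    }
    return DfaResult(
        confusion=conf,
        overall_rate_pct=100.0 * correct / total,
        per_class_rate_pct=per_class,
        priors_used=prior_map,
        features=feature_names,
    )


@dataclass
class StepwiseResult:
    order: list  # features in order of inclusion
    accuracy_trace: list  # LOOCV correctness (fraction) after each inclusion

    def ranking(self) -> list:
        return list(self.order)


def stepwise_select(
    features: pd.DataFrame,
    labels,
    improvement_min: float = 0.05,
    priors="proportional",
) -> StepwiseResult:
    """Forward stepwise feature ranking by leave-one-out QDA correctness.

    At each step the candidate feature that most improves the LOOCV
    correct-classification fraction is added; selection stops when the best
    improvement falls below ``improvement_min``.  Candidates whose
    per-class covariance is singular in any fold are skipped; if every
    candidate fails on the first step, an error is raised.
    """
    if features.shape[1] < 2:
        raise ValueError("stepwise selection needs >= 2 candidate features")
    y = np.asarray(labels)
    remaining = list(features.columns)
    selected: list = []
    trace: list = []
    current = 0.0
    while remaining:
        best_feat, best_acc = None, -np.inf
        for feat in remaining:
            cols = selected + [feat]
            try:
                res = qda_loocv(features[cols], y, priors=priors)
            except ValueError:
                continue
            acc = res.overall_rate_pct / 100.0
            if acc > best_acc:
                best_feat, best_acc = feat, acc
        if best_feat is None:
            if not selected:
                raise ValueError("no feature admits a non-singular QDA fit")
            break
        # the first feature is always accepted; afterwards each addition
        # must improve LOOCV correctness by at least improvement_min
        if selected and best_acc - current < improvement_min:
            break
        selected.append(best_feat)
        remaining.remove(best_feat)
        trace.append(best_acc)
        current = best_acc
    return StepwiseResult(order=selected, accuracy_trace=trace)


# ---------------------------------------------------------------------------
# covariance / normality diagnostics


def _mardia(X: np.ndarray) -> dict:
    """Mardia's multivariate skewness and kurtosis tests."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / n  # ML covariance, per Mardia's definition
    Sinv = np.linalg.inv(S)
    G = Xc @ Sinv @ Xc.T
    b1 = float((G**3).sum()) / n**2
    b2 = float(np.mean(np.diag(G) ** 2))
    df_skew = p * (p + 1) * (p + 2) / 6.0
    stat_skew = n * b1 / 6.0
    p_skew = float(sps.chi2.sf(stat_skew, df_skew))
    stat_kurt = (b2 - p * (p + 2)) / np.sqrt(8.0 * p * (p + 2) / n)
    p_kurt = float(2 * sps.norm.sf(abs(stat_kurt)))
    return {
        "skew_stat": stat_skew,
        "skew_df": df_skew,
        "skew_p": p_skew,
        "kurt_z": float(stat_kurt),
        "kurt_p": p_kurt,
    }


def covariance_diagnostics(features, labels) -> dict:
    """Box's M homogeneity test plus Mardia's multivariate normality.

    Box's M (chi-square approximation) tests equality of the class
    covariance matrices — its rejection motivates quadratic over linear
    discriminant analysis.  Normality is assessed with Mardia's skewness
    and kurtosis on class-mean-centred residuals (the Gaussian assumption
    actually made by QDA).
    """
    if isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=float)
        cols = list(features.columns)
    else:
        X = np.asarray(features, dtype=float)
        cols = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(labels)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("covariance diagnostics need >= 2 classes")
    p = X.shape[1]
    for c in classes:
        nc = int(np.sum(y == c))
        if nc <= p:
            raise ValueError(f"class {c!r} has too few rows for a covariance")
        if np.linalg.matrix_rank(np.cov(X[y == c], rowvar=False)) < p:
            raise ValueError(f"singular covariance in class {c!r}")

    import pingouin as pg

    df = pd.DataFrame(X, columns=cols)
    df["_group"] = y
    bm = pg.box_m(df, dvs=cols, group="_group")
    row = bm.iloc[0]
    resid = np.vstack([X[y == c] - X[y == c].mean(axis=0) for c in classes])
    return {
        "box_m": {
            "chi2": float(row["Chi2"]),
            "df": float(row["df"]),
            "p": float(row["pval"]),
        },
        "mardia": _mardia(resid),
    }
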