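"""Statistical workflow over a per-drawing metrics table.

Two analysis arms mirror the study design:

* **inter-individual** — PCA over the 11 quantitative variables of all
  drawings (correlation matrix, components retained while their
  eigenvalue exceeds 1), then a Kruskal-Wallis omnibus per retained
  dimension with pairwise two-sided rank-sum post hocs, Benjamini-
  Hochberg corrected;
* **longitudinal** — a second PCA restricted to the prolific
  individual, then per dimension a linear model ``score ~ season +
  period`` whose per-term p-values come from Monte Carlo permutation of
  the response (partial-F statistic, 10,000 permutations by default),
  with generalized variance-inflation-factor diagnostics and pairwise
  permutation post hocs across seasons.

The qualitative main-colour variable is analysed separately with
chi-square goodness-of-fit tests per group against a uniform use of
the colours observed in the dataset.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.multivariate.factor_rotation import rotate_factors
from statsmodels.stats.multitest import multipletests

from .gridmetrics import METRIC_COLUMNS, QUANTITATIVE_VARS

__all__ = [
    "AnalysisConfig",
    "CorrelationReport",
    "PCAModel",
    "GroupTestResult",
    "PermLMResult",
    "ColourTestResult",
    "AnalysisReport",
    "correlation_screen",
    "pca_fit",
    "kruskal_with_posthoc",
    "permutation_lm",
    "vif",
    "pairwise_permutation_posthoc",
    "chisq_main_colour",
    "run_full_analysis",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of the full statistical run."""

    B: int = 10_000                    # Monte Carlo permutations
    alpha: float = 0.05
    seed: int = 0
    eigenvalue_threshold: float = 1.0  # Kaiser retention rule
    correlation_threshold: float = 0.8
    rotation: str = "none"             # or "varimax"
    longitudinal_individual: str | None = None  # None: most prolific


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    matrix: pd.DataFrame
    flagged: list[tuple[str, str, float]]      # |r| strictly above threshold
    undefined: list[tuple[str, str]]           # constant-column pairs
    threshold: float

    @property
    def kept(self) -> list[str]:
        return list(self.matrix.columns)


def correlation_screen(metrics: pd.DataFrame, threshold: float = 0.8) -> CorrelationReport:
    """Pairwise Pearson correlations with flags for |r| > threshold.

    Report only: the screen never drops variables automatically.  Pairs
    involving a constant column have undefined correlation and are
    reported as such.
    """
    if metrics.shape[1] < 2 or metrics.shape[0] < 3:
        raise ValueError("need at least 2 variables and 3 rows")
    corr = metrics.corr()
    flagged, undefined = [], []
    cols = list(metrics.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isnan(r):
                undefined.append((a, b))
            elif abs(r) - threshold > 1e-12:  # strictly above, float-robust
                flagged.append((a, b, float(r)))
    return CorrelationReport(corr, flagged, undefined, threshold)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Correlation-matrix PCA with eigenvalue-above-1 retention."""

    variables: list[str]
    eigenvalues: np.ndarray            # all components, nonincreasing
    explained_pct: np.ndarray          # all components, sums to 100
    retained: int
    loadings: pd.DataFrame             # variables x retained dims (corr-scaled)
    scores: pd.DataFrame               # drawings x retained dims
    rotation: str
    retention_rule: str
    mean: np.ndarray
    std: np.ndarray
    components: np.ndarray             # retained unit eigenvectors (p x k)

    @property
    def explained_pct_retained(self) -> np.ndarray:
        return self.explained_pct[: self.retained]

    def dim_names(self) -> list[str]:
        return list(self.scores.columns)


def pca_fit(
    metrics: pd.DataFrame,
    standardize: bool = True,
    rotation: str = "none",
    eigenvalue_threshold: float = 1.0,
) -> PCAModel:
    """PCA of the metrics matrix on the correlation matrix.

    Variables are centred and scaled, components with eigenvalue above
    ``eigenvalue_threshold`` are retained, and per-drawing scores are
    emitted for the downstream group tests.  ``rotation="varimax"``
    rotates the retained loadings (and scores accordingly).
    """
    if metrics.isna().any().any():
        raise ValueError("metrics matrix contains missing values")
    if metrics.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    x = metrics.to_numpy(dtype=float)
    n, p = x.shape
    if n < p:
        warnings.warn(f"fewer rows ({n}) than variables ({p}); PCA still computed")
    sd = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [metrics.columns[i] for i in zero]
        raise ValueError(f"zero-variance variable(s): {names}")
    mean = x.mean(axis=0)
    z = (x - mean) / sd if standardize else x - mean
    r = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(r)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0.0, None), eigvec[:, order]
    # deterministic sign: largest-magnitude coefficient positive
    for k in range(p):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] *= -1.0
    explained = eigval / eigval.sum() * 100.0
    retained = int(np.count_nonzero(eigval > eigenvalue_threshold))
    k = max(retained, 1)
    comps = eigvec[:, :k]
    load = comps * np.sqrt(eigval[:k])
    scores = z @ comps
    if rotation == "varimax" and k > 1:
        load, t = rotate_factors(load, "varimax")
        scores = scores @ t
    elif rotation not in ("none", "varimax"):
        raise ValueError(f"unknown rotation {rotation!r}")
    dims = [f"Dim{i + 1}" for i in range(k)]
    return PCAModel(
        variables=list(metrics.columns),
        eigenvalues=eigval,
        explained_pct=explained,
        retained=retained,
        loadings=pd.DataFrame(load, index=metrics.columns, columns=dims),
        scores=pd.DataFrame(scores, index=metrics.index, columns=dims),
        rotation=rotation,
        retention_rule=f"eigenvalue > {eigenvalue_threshold}",
        mean=mean,
        std=sd,
        components=comps,
    )


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def _letter_display(groups: list[str], sig: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Compact letter display: groups sharing a letter do not differ."""
    columns: list[set[str]] = []
    for g, h in [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]:
        if sig[(g, h)]:
            continue
        if any(g in col and h in col for col in columns):
            continue
        merged = False
        for col in columns:
            if all(not sig[tuple(sorted((m, x)))] for m in (g, h) for x in col if x not in (g, h)):
                col.update((g, h))
                merged = True
                break
        if not merged:
            columns.append({g, h})
    for g in groups:  # isolated groups get their own letter
        if not any(g in col for col in columns):
            columns.append({g})
    columns = [c for c in columns if not any(c < d for d in columns)]
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        for g in sorted(col):
            letters[g] += chr(ord("a") + i)
    return {g: "".join(sorted(s)) for g, s in letters.items()}


@dataclass
class GroupTestResult:
    statistic: float
    df: int
    p_value: float
    groups: list[str]
    pairwise_raw: pd.DataFrame
    pairwise_adj: pd.DataFrame          # Benjamini-Hochberg adjusted
    letters: dict[str, str]
    excluded: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "statistic": round(self.statistic, 6),
            "df": self.df,
            "p_value": self.p_value,
            "groups": self.groups,
            "pairwise_adj": {
                f"{a}|{b}": float(self.pairwise_adj.loc[a, b])
                for i, a in enumerate(self.groups)
                for b in self.groups[i + 1:]
            },
            "letters": self.letters,
            "excluded": self.excluded,
        }


def kruskal_with_posthoc(
    values: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    alpha: float = 0.05,
) -> GroupTestResult:
    """Kruskal-Wallis omnibus plus pairwise rank-sum post hocs.

    The omnibus is tie-corrected; all group pairs are then compared
    with two-sided Wilcoxon rank-sum tests and the p-values adjusted by
    Benjamini-Hochberg across pairs.  Groups with fewer than two
    observations are excluded with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = sorted(pd.unique(groups).tolist())
    samples = {g: values[groups == g] for g in names}
    excluded = [g for g, v in samples.items() if len(v) < 2]
    if excluded:
        warnings.warn(f"groups excluded with <2 observations: {excluded}")
    names = [g for g in names if g not in excluded]
    if len(names) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    stat, p = sps.kruskal(*[samples[g] for g in names])
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    raw = np.array(
        [sps.mannwhitneyu(samples[a], samples[b], alternative="two-sided").pvalue for a, b in pairs]
    )
    adj = _benjamini_hochberg(raw)
    raw_m = pd.DataFrame(np.nan, index=names, columns=names)
    adj_m = pd.DataFrame(np.nan, index=names, columns=names)
    sig = {}
    for (a, b), pr, pa in zip(pairs, raw, adj):
        raw_m.loc[a, b] = raw_m.loc[b, a] = pr
        adj_m.loc[a, b] = adj_m.loc[b, a] = pa
        sig[(a, b)] = pa < alpha
    letters = _letter_display(names, sig)
    return GroupTestResult(float(stat), len(names) - 1, float(p), names, raw_m, adj_m, letters, excluded)


# ---------------------------------------------------------------------------
# permutation linear model
# ---------------------------------------------------------------------------

def _design(season: pd.Series, period: pd.Series) -> tuple[np.ndarray, dict[str, list[int]], list[str]]:
    """Intercept + treatment-coded season + numeric period design."""
    levels = sorted(pd.unique(season).tolist())
    cols = [np.ones(len(season))]
    names = ["intercept"]
    for lv in levels[1:]:
        cols.append((season == lv).to_numpy(dtype=float))
        names.append(f"season[{lv}]")
    season_idx = list(range(1, len(cols)))
    cols.append(pd.to_numeric(period).to_numpy(dtype=float))
    names.append("period")
    x = np.column_stack(cols)
    terms = {"season": season_idx, "period": [x.shape[1] - 1]}
    return x, terms, names


def vif(design: pd.DataFrame, terms: dict[str, list[str]] | None = None) -> dict[str, float]:
    """Generalized variance inflation factors of a predictor matrix.

    For a single-column term this is the classic ``1 / (1 - R^2)`` of
    that predictor regressed on all others; multi-column terms (e.g. a
    dummy-coded factor) use the determinant form
    ``det(R_term) * det(R_other) / det(R_full)``.  Perfectly collinear
    predictors report ``inf``.
    """
    if design.shape[1] < 2:
        raise ValueError("need at least 2 predictor columns")
    if terms is None:
        terms = {c: [c] for c in design.columns}
    x = design.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant predictor column")
    r = np.corrcoef(x, rowvar=False)
    cols = {c: i for i, c in enumerate(design.columns)}
    det_full = np.linalg.det(r)
    out = {}
    for term, members in terms.items():
        idx = [cols[m] for m in members]
        rest = [i for i in range(len(cols)) if i not in idx]
        det_t = np.linalg.det(r[np.ix_(idx, idx)])
        det_r = np.linalg.det(r[np.ix_(rest, rest)]) if rest else 1.0
        if det_full <= 1e-12:
            out[term] = float("inf")
        else:
            out[term] = float(det_t * det_r / det_full)
    return out


@dataclass
class PermLMResult:
    response: str
    n: int
    B: int
    seed: int
    coefficients: dict[str, float]
    r_squared: float
    f_observed: dict[str, float]       # partial F per term
    term_df: dict[str, int]
    p_perm: dict[str, float]           # (1 + r) / (1 + B)
    vif: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "n": self.n,
            "B": self.B,
            "seed": self.seed,
            "coefficients": {k: round(v, 8) for k, v in self.coefficients.items()},
            "r_squared": round(self.r_squared, 8),
            "f_observed": {k: round(v, 8) for k, v in self.f_observed.items()},
            "term_df": self.term_df,
            "p_perm": self.p_perm,
            "vif": {k: round(v, 8) for k, v in self.vif.items()},
        }


def _rss(q: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of column(s) of y against design with
    orthonormal column basis q."""
    fit = q.T @ y
    return (y * y).sum(axis=0) - (fit * fit).sum(axis=0)


def permutation_lm(
    y: np.ndarray | pd.Series,
    season: pd.Series,
    period: pd.Series,
    B: int = 10_000,
    seed: int = 0,
    response: str = "y",
) -> PermLMResult:
    """Linear model ``y ~ season + period`` with permutation p-values.

    The observed statistic for each term is its partial F (extra sum of
    squares over the model without the term).  The null distribution
    permutes the raw response ``B`` times and refits; p-values use the
    add-one convention ``(1 + #{F* >= F_obs}) / (1 + B)`` and therefore
    never reach zero.  Reproducible given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values")
    season = pd.Series(np.asarray(season))
    period = pd.Series(np.asarray(period))
    x, terms, names = _design(season, period)
    n, p = x.shape
    empty = [t for t, idx in terms.items() if not idx]
    if empty:
        raise ValueError(f"rank-deficient design; aliased term(s): {empty} (single level)")
    if np.linalg.matrix_rank(x) < p:
        aliased = [t for t, idx in terms.items()
                   if np.linalg.matrix_rank(np.delete(x, idx, axis=1)) == np.linalg.matrix_rank(x)]
        raise ValueError(f"rank-deficient design; aliased term(s): {aliased}")

    q_full, _ = np.linalg.qr(x)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    rss_full = float(_rss(q_full, y[:, None])[0])
    tss = float(((y - y.mean()) ** 2).sum())
    df_resid = n - p

    q_reduced = {t: np.linalg.qr(np.delete(x, idx, axis=1))[0] for t, idx in terms.items()}
    term_df = {t: len(idx) for t, idx in terms.items()}

    def partial_f(yy: np.ndarray) -> dict[str, np.ndarray]:
        rf = _rss(q_full, yy)
        out = {}
        for t, qr in q_reduced.items():
            out[t] = ((_rss(qr, yy) - rf) / term_df[t]) / (rf / df_resid)
        return out

    f_obs = {t: float(v[0]) for t, v in partial_f(y[:, None]).items()}

    rng = np.random.default_rng(seed)
    perms = np.tile(y, (B, 1))
    rng.permuted(perms, axis=1, out=perms)
    f_perm = partial_f(perms.T)
    p_perm = {
        t: float((1 + np.count_nonzero(f_perm[t] >= f_obs[t] - 1e-12)) / (1 + B)) for t in terms
    }

    predictors = pd.DataFrame(x[:, 1:], columns=names[1:])
    gvif = vif(predictors, {t: [names[i] for i in idx] for t, idx in terms.items()})
    return PermLMResult(
        response=response,
        n=n,
        B=B,
        seed=seed,
        coefficients=dict(zip(names, (float(b) for b in beta))),
        r_squared=1.0 - rss_full / tss if tss > 0 else 0.0,
        f_observed=f_obs,
        term_df=term_df,
        p_perm=p_perm,
        vif=gvif,
    )


def pairwise_permutation_posthoc(
    y: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    B: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise permutation tests on group mean differences, BH adjusted.

    For each pair of groups the observed |mean difference| is compared
    with its distribution under ``B`` random relabellings of the pooled
    observations; p-values use the add-one convention and are then
    Benjamini-Hochberg corrected across pairs.  Returns the symmetric
    adjusted p-value matrix.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    names = sorted(pd.unique(groups).tolist())
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    raw = []
    for a, b in pairs:
        ya, yb = y[groups == a], y[groups == b]
        pooled = np.concatenate([ya, yb])
        obs = abs(ya.mean() - yb.mean())
        perms = np.tile(pooled, (B, 1))
        rng.permuted(perms, axis=1, out=perms)
        da = perms[:, : len(ya)].mean(axis=1) - perms[:, len(ya):].mean(axis=1)
        raw.append((1 + np.count_nonzero(np.abs(da) >= obs - 1e-12)) / (1 + B))
    adj = _benjamini_hochberg(np.array(raw))
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for (a, b), pa in zip(pairs, adj):
        out.loc[a, b] = out.loc[b, a] = float(pa)
    return out


# ---------------------------------------------------------------------------
# main-colour chi-square
# ---------------------------------------------------------------------------

@dataclass
class ColourTestResult:
    group: str
    counts: dict[str, int]             # per colour category
    statistic: float
    df: int
    p_value: float
    modal_colour: str
    modal_share: float
    small_expected: bool               # expected count per cell below 5

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "counts": self.counts,
            "statistic": round(self.statistic, 6),
            "df": self.df,
            "p_value": self.p_value,
            "modal_colour": self.modal_colour,
            "modal_share": round(self.modal_share, 6),
            "small_expected": self.small_expected,
        }


def chisq_main_colour(
    main_colours: pd.Series,
    groups: pd.Series,
    categories: list | None = None,
) -> list[ColourTestResult]:
    """Per-group chi-square of main-colour counts against uniform use.

    The null is a uniform distribution over the colour categories
    observed anywhere in the dataset (or the explicit ``categories``),
    so the degrees of freedom are shared across groups.  Groups whose
    expected count per cell falls below 5 carry a small-sample flag.
    """
    main_colours = pd.Series(np.asarray(main_colours, dtype=object))
    groups = pd.Series(np.asarray(groups, dtype=object))
    valid = main_colours.notna()
    if categories is None:
        categories = sorted(pd.unique(main_colours[valid]).tolist())
    if not categories:
        raise ValueError("no main colours observed")
    out = []
    for g in sorted(pd.unique(groups).tolist()):
        sel = (groups == g) & valid
        counts = main_colours[sel].value_counts()
        obs = np.array([int(counts.get(c, 0)) for c in categories], dtype=float)
        n = obs.sum()
        if n == 0:
            continue
        stat, p = sps.chisquare(obs)
        modal = int(np.argmax(obs))
        out.append(
            ColourTestResult(
                group=str(g),
                counts={str(c): int(v) for c, v in zip(categories, obs)},
                statistic=float(stat),
                df=len(categories) - 1,
                p_value=float(p),
                modal_colour=str(categories[modal]),
                modal_share=float(obs[modal] / n),
                small_expected=bool(n / len(categories) < 5),
            )
        )
    return out


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """Bundle of every result of a full analysis run."""

    config: AnalysisConfig
    correlation: CorrelationReport
    pca_inter: PCAModel | None
    kruskal_dims: dict[str, GroupTestResult]
    kruskal_vars: dict[str, GroupTestResult]
    pca_long: PCAModel | None
    perm_lm_dims: dict[str, PermLMResult]
    perm_lm_vars: dict[str, PermLMResult]
    season_posthoc_dims: dict[str, pd.DataFrame]
    colour_by_individual: list[ColourTestResult]
    colour_by_season: list[ColourTestResult]
    longitudinal_individual: str | None
    log: list[str]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        loadings = []
        for name, model in (("inter", self.pca_inter), ("longitudinal", self.pca_long)):
            if model is None:
                continue
            df = model.loadings.copy()
            df.insert(0, "analysis", name)
            df.insert(1, "variable", df.index)
            loadings.append(df)
        if loadings:
            pd.concat(loadings).to_csv(out / "pca_loadings.csv", index=False)
        scores = []
        for name, model in (("inter", self.pca_inter), ("longitudinal", self.pca_long)):
            if model is None:
                continue
            df = model.scores.copy()
            df.insert(0, "analysis", name)
            df.insert(1, "drawing_id", df.index)
            scores.append(df)
        if scores:
            pd.concat(scores).to_csv(out / "pca_scores.csv", index=False)
        (out / "group_tests.json").write_text(
            json.dumps(
                {
                    "dimensions": {k: v.to_dict() for k, v in self.kruskal_dims.items()},
                    "variables": {k: v.to_dict() for k, v in self.kruskal_vars.items()},
                },
                indent=1,
                sort_keys=True,
            )
        )
        (out / "perm_lm.json").write_text(
            json.dumps(
                {
                    "dimensions": {k: v.to_dict() for k, v in self.perm_lm_dims.items()},
                    "variables": {k: v.to_dict() for k, v in self.perm_lm_vars.items()},
                    "season_posthoc": {
                        k: {
                            f"{a}|{b}": float(m.loc[a, b])
                            for i, a in enumerate(m.index)
                            for b in m.index[i + 1:]
                        }
                        for k, m in self.season_posthoc_dims.items()
                    },
                },
                indent=1,
                sort_keys=True,
            )
        )
        (out / "colour_tests.json").write_text(
            json.dumps(
                {
                    "by_individual": [c.to_dict() for c in self.colour_by_individual],
                    "by_season_longitudinal": [c.to_dict() for c in self.colour_by_season],
                },
                indent=1,
                sort_keys=True,
            )
        )
        (out / "run_log.txt").write_text("\n".join(self.log) + "\n")


def _check_schema(metrics: pd.DataFrame) -> None:
    missing = [c for c in METRIC_COLUMNS if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table missing column(s): {missing}")


def run_full_analysis(
    metrics: pd.DataFrame | str | Path,
    config: AnalysisConfig = AnalysisConfig(),
) -> AnalysisReport:
    """Run the complete statistical workflow on a metrics table.

    Executes the correlation screen, the inter-individual arm (PCA +
    per-dimension and per-variable Kruskal-Wallis with post hocs), the
    longitudinal arm (separate PCA on the flagged individual, per-
    dimension and per-variable permutation linear models of season and
    period with VIF diagnostics and season post hocs), and the
    main-colour chi-square tests.
    """
    if not isinstance(metrics, pd.DataFrame):
        metrics = pd.read_csv(metrics)
    _check_schema(metrics)
    log = [
        f"seed={config.seed}",
        f"B={config.B}",
        f"alpha={config.alpha}",
        f"rotation={config.rotation}",
        f"n_drawings={len(metrics)}",
        f"variables={QUANTITATIVE_VARS}",
    ]
    quant = metrics[QUANTITATIVE_VARS].astype(float)
    corr = correlation_screen(quant, config.correlation_threshold)
    log.append(
        f"correlation screen: {len(corr.flagged)} pair(s) above |r|={config.correlation_threshold}"
    )

    # inter-individual arm
    counts = metrics["individual"].value_counts()
    usable = counts[counts >= 2]
    pca_inter = None
    kruskal_dims: dict[str, GroupTestResult] = {}
    kruskal_vars: dict[str, GroupTestResult] = {}
    if len(usable) >= 2:
        pca_inter = pca_fit(
            quant.set_axis(metrics["drawing_id"]),
            rotation=config.rotation,
            eigenvalue_threshold=config.eigenvalue_threshold,
        )
        log.append(
            f"inter-individual PCA: {pca_inter.retained} dimension(s) retained "
            f"({pca_inter.explained_pct_retained.sum():.1f}% variance)"
        )
        for dim in pca_inter.dim_names():
            kruskal_dims[dim] = kruskal_with_posthoc(
                pca_inter.scores[dim].to_numpy(), metrics["individual"], config.alpha
            )
        for var in QUANTITATIVE_VARS:
            kruskal_vars[var] = kruskal_with_posthoc(
                quant[var].to_numpy(), metrics["individual"], config.alpha
            )
    else:
        log.append("inter-individual arm skipped: fewer than 2 individuals with >= 2 drawings")

    # longitudinal arm
    long_ind = config.longitudinal_individual or (counts.idxmax() if len(counts) else None)
    sub = metrics[metrics["individual"] == long_ind]
    pca_long = None
    perm_lm_dims: dict[str, PermLMResult] = {}
    perm_lm_vars: dict[str, PermLMResult] = {}
    posthoc: dict[str, pd.DataFrame] = {}
    if long_ind is not None and len(sub) >= 12 and sub["season"].nunique() >= 2:
        sub_quant = sub[QUANTITATIVE_VARS].astype(float)
        pca_long = pca_fit(
            sub_quant.set_axis(sub["drawing_id"]),
            rotation=config.rotation,
            eigenvalue_threshold=config.eigenvalue_threshold,
        )
        log.append(
            f"longitudinal PCA ({long_ind}): {pca_long.retained} dimension(s) retained "
            f"({pca_long.explained_pct_retained.sum():.1f}% variance)"
        )
        for i, dim in enumerate(pca_long.dim_names()):
            res = permutation_lm(
                pca_long.scores[dim].to_numpy(),
                sub["season"],
                sub["period"],
                B=config.B,
                seed=config.seed + i,
                response=dim,
            )
            perm_lm_dims[dim] = res
            posthoc[dim] = pairwise_permutation_posthoc(
                pca_long.scores[dim].to_numpy(),
                sub["season"].to_numpy(),
                B=config.B,
                seed=config.seed + 100 + i,
                alpha=config.alpha,
            )
        for i, var in enumerate(QUANTITATIVE_VARS):
            perm_lm_vars[var] = permutation_lm(
                sub_quant[var].to_numpy(),
                sub["season"],
                sub["period"],
                B=config.B,
                seed=config.seed + 200 + i,
                response=var,
            )
    else:
        log.append("longitudinal arm skipped: not enough drawings or seasonal spread")

    colour_ind = chisq_main_colour(metrics["main_colour"], metrics["individual"])
    colour_season = (
        chisq_main_colour(sub["main_colour"], sub["season"]) if len(sub) else []
    )
    log.append("analysis complete")
    return AnalysisReport(
        config=config,
        correlation=corr,
        pca_inter=pca_inter,
        kruskal_dims=kruskal_dims,
        kruskal_vars=kruskal_vars,
        pca_long=pca_long,
        perm_lm_dims=perm_lm_dims,
        perm_lm_vars=perm_lm_vars,
        season_posthoc_dims=posthoc,
        colour_by_individual=colour_ind,
        colour_by_season=colour_season,
        longitudinal_individual=long_ind,
        log=log,
    )
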