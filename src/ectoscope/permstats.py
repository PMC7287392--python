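"""Permutation-based factorial inference for the repeated-measures design.

The design crosses three between-fish factors (day length, thyroid status,
acclimation temperature) with one within-fish factor (acute test
temperature; every fish is measured at both levels). With two-level,
sum-to-zero coded factors the mixed model splits exactly into two
orthogonal strata per fish:

    m_i = (y_i,cold + y_i,warm) / 2    between-fish stratum
    c_i = (y_i,warm - y_i,cold) / 2    within-fish stratum

Terms not involving test temperature are tested by regressing ``m`` on the
full between-fish design (intercept + 7 effect columns); terms involving
it are tested in the ``c`` regression, where the intercept carries the
test-temperature main effect and each between column carries its
interaction with test temperature. This is the classical split-plot
decomposition; fish identity is the blocking factor separating the two
error strata. F statistics use marginal (drop-term) sums of squares, which
coincide with sequential sums of squares in balanced designs.

P-values come from Freedman–Lane residual permutation within the
appropriate stratum: residuals of the reduced model (without the tested
term) are permuted across fish for between-stratum terms, and sign-flipped
per fish for within-stratum terms (flipping a fish's test-temperature
contrast), then added back to the reduced-model fit and the statistic is
recomputed. p = (#{F* >= F_obs} + 1) / (B + 1); exhaustive enumeration is
used automatically when the total number of arrangements does not exceed
the requested B, and is then exact (no +1 correction).

Effect sizes are Cohen's d (pooled SD, n−1 weights) with bootstrap 95%
confidence intervals (BCa by default), oriented so a positive d means a
positive effect of thyroid hormone where applicable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations, product

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AliasingError,
    InvalidInputError,
    MissingPairError,
    UndefinedEffectError,
)
from .factors import (
    BETWEEN_FACTORS,
    LEVELS,
    WITHIN_FACTOR,
    code_level,
    model_terms,
    term_name,
)

DEFAULT_N_PERMUTATIONS = 4999
DEFAULT_N_BOOT = 2000
_F_TOL = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """Specification of the factorial permutation analysis for one response."""

    response: str
    n_permutations: int = DEFAULT_N_PERMUTATIONS
    seed: int = 0
    subject: str = "fish_id"
    within: str = WITHIN_FACTOR
    between: tuple[str, ...] = BETWEEN_FACTORS

    @property
    def terms(self) -> list[tuple[str, ...]]:
        return model_terms()


@dataclass
class FactorialFit:
    """Observed per-term F statistics and the stratum decomposition."""

    terms: list[str]
    f_stats: dict[str, float]
    ss: dict[str, float]
    stratum: dict[str, str]  # 'between' or 'within'
    df2: dict[str, int]  # residual df per stratum
    n_subjects: int
    # internals reused by the permutation engine
    _design: dict = field(repr=False, default=None)  # stratum -> (X, names)
    _y: dict = field(repr=False, default=None)  # stratum -> response vector
    _test_col: dict[str, int] = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "stratum": [self.stratum[t] for t in self.terms],
                "F": [self.f_stats[t] for t in self.terms],
                "ss": [self.ss[t] for t in self.terms],
                "df1": 1,
                "df2": [self.df2[self.stratum[t]] for t in self.terms],
            }
        )


@dataclass
class PermutationAnovaResult:
    """Per-term observed F and permutation p (machine-readable ANOVA table)."""

    table: pd.DataFrame  # term, stratum, F, df1, df2, p_perm, n_perm, exhaustive
    seed: int

    def p(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p_perm"])


@dataclass
class ContrastResult:
    description: str
    estimate: float
    p_perm: float
    n_permutations: int
    exhaustive: bool
    seed: int


@dataclass
class EffectSizeResult:
    description: str
    cohens_d: float
    ci_low: float
    ci_high: float
    n_a: int
    n_b: int
    n_boot: int
    ci_method: str
    seed: int


# ---------------------------------------------------------------------------
# stratum decomposition and observed fit


def _decompose(data: pd.DataFrame, spec: ModelSpec):
    """Split long-format rows into per-fish means and within contrasts."""
    needed = [spec.subject, spec.within, *spec.between, spec.response]
    missing = [col for col in needed if col not in data.columns]
    if missing:
        raise InvalidInputError(f"data missing columns {missing}")
    d = data.sort_values([spec.subject, spec.within], kind="mergesort")
    y = pd.to_numeric(d[spec.response], errors="raise").to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise InvalidInputError(f"non-finite values in response {spec.response!r}")

    counts = d.groupby(spec.subject, sort=True)[spec.within].agg(["count", "nunique"])
    bad = counts[(counts["count"] != 2) | (counts["nunique"] != 2)]
    if len(bad):
        raise MissingPairError(
            f"subjects without exactly one row per {spec.within} level: "
            f"{bad.index.tolist()[:5]}"
        )
    per_fish = d.drop_duplicates(spec.subject).reset_index(drop=True)
    incons = d.groupby(spec.subject)[list(spec.between)].nunique()
    if (incons != 1).any().any():
        raise InvalidInputError("between-factor levels differ within a subject")

    w_code = d[spec.within].map(lambda l: code_level(spec.within, l)).to_numpy()
    n_fish = len(per_fish)
    y2 = y.reshape(n_fish, 2)
    w2 = w_code.reshape(n_fish, 2)
    m = y2.mean(axis=1)
    c = (y2 * w2).sum(axis=1) / 2.0
    return per_fish, m, c


def _between_matrix(per_fish: pd.DataFrame, spec: ModelSpec):
    """Intercept + 7 sum-to-zero effect columns for the between design."""
    codes = {
        f: per_fish[f].map(lambda l: code_level(f, l)).to_numpy()
        for f in spec.between
    }
    cols = [np.ones(len(per_fish))]
    names = ["(intercept)"]
    for k in (1, 2, 3):
        for combo in combinations(spec.between, k):
            col = np.ones(len(per_fish))
            for f in combo:
                col = col * codes[f]
            cols.append(col)
            names.append(term_name(combo))
    xb = np.column_stack(cols)
    if np.linalg.matrix_rank(xb) < xb.shape[1]:
        cells = per_fish.groupby(list(spec.between), observed=True).size()
        expected = set(product(*(LEVELS[f] for f in spec.between)))
        empty = sorted(expected - set(cells.index))
        raise AliasingError(
            f"between design is rank deficient; empty cells: {empty}"
        )
    return xb, names


def _rss(q: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of y (vector or n x B matrix) on span(Q)."""
    proj = q.T @ y
    return np.sum(y * y, axis=0) - np.sum(proj * proj, axis=0)


def fit_factorial_model(data: pd.DataFrame, spec: ModelSpec) -> FactorialFit:
    """Observed drop-term F statistics for all 14 terms.

    Between-stratum terms are tested on per-fish means against the full
    8-column between design (df2 = n_fish − 8). Within-stratum terms are
    tested on per-fish test-temperature contrasts against a 7-column
    design: the between three-way column is omitted there because it would
    carry the four-way interaction, which is excluded from the model and
    therefore pooled into the within-stratum error (df2 = n_fish − 7).
    """
    per_fish, m, c = _decompose(data, spec)
    xb, names = _between_matrix(per_fish, spec)
    n_fish = xb.shape[0]
    three_way_col = names.index(term_name(spec.between))
    xc = np.delete(xb, three_way_col, axis=1)
    names_c = [n for i, n in enumerate(names) if i != three_way_col]
    design = {"between": (xb, names), "within": (xc, names_c)}
    responses = {"between": m, "within": c}
    df2 = {"between": n_fish - xb.shape[1], "within": n_fish - xc.shape[1]}
    if min(df2.values()) < 1:
        raise InvalidInputError(
            f"{n_fish} subjects leave no residual degrees of freedom"
        )

    f_stats, ss_map, stratum, test_col = {}, {}, {}, {}
    terms = [term_name(t) for t in spec.terms]
    q_full = {s: np.linalg.qr(x)[0] for s, (x, _) in design.items()}
    for t in spec.terms:
        name = term_name(t)
        if spec.within in t:
            stratum[name] = "within"
            between_part = tuple(f for f in t if f != spec.within)
            x, xnames = design["within"]
            col = (
                0
                if not between_part
                else xnames.index(term_name(between_part))
            )
        else:
            stratum[name] = "between"
            x, xnames = design["between"]
            col = xnames.index(name)
        y = responses[stratum[name]]
        test_col[name] = col
        qr_red, _ = np.linalg.qr(np.delete(x, col, axis=1))
        rss_full = float(_rss(q_full[stratum[name]], y))
        rss_red = float(_rss(qr_red, y))
        ss = max(rss_red - rss_full, 0.0)
        ss_map[name] = ss
        scale = max(float(y @ y), 1.0)
        if rss_full > 1e-12 * scale:
            f_stats[name] = ss / (rss_full / df2[stratum[name]])
        else:
            # saturated (noiseless) fit: a term is either exactly present
            # or exactly absent
            f_stats[name] = np.inf if ss > 1e-12 * scale else 0.0

    return FactorialFit(
        terms=terms,
        f_stats=f_stats,
        ss=ss_map,
        stratum=stratum,
        df2=df2,
        n_subjects=n_fish,
        _design=design,
        _y=responses,
        _test_col=test_col,
    )


# ---------------------------------------------------------------------------
# permutation engine


def _all_sign_vectors(n: int) -> np.ndarray:
    bits = np.arange(2**n, dtype=np.int64)
    return 1.0 - 2.0 * ((bits[:, None] >> np.arange(n)) & 1)


def permutation_test(data: pd.DataFrame, spec: ModelSpec) -> PermutationAnovaResult:
    """Freedman–Lane permutation p-values for all 14 terms.

    Each term draws its permutations from an independent substream of
    ``spec.seed`` (in canonical term order), so results are deterministic
    given the seed and invariant to input row order. Exhaustive mode is
    selected per term when the number of distinct arrangements (n! whole-
    fish permutations, or 2^n sign flips) is at most ``n_permutations``.
    """
    fit = fit_factorial_model(data, spec)
    if spec.n_permutations < 99:
        import warnings

        warnings.warn(
            f"n_permutations={spec.n_permutations} gives coarse p-value "
            "resolution (< 1/100)",
            stacklevel=2,
        )
    streams = np.random.SeedSequence(spec.seed).spawn(len(fit.terms))

    rows = []
    for name, ss_stream in zip(fit.terms, streams):
        rng = np.random.default_rng(ss_stream)
        col = fit._test_col[name]
        x, _ = fit._design[fit.stratum[name]]
        n = x.shape[0]
        qf, _ = np.linalg.qr(x)
        y = fit._y[fit.stratum[name]]
        x_red = np.delete(x, col, axis=1)
        qr_red, _ = np.linalg.qr(x_red)
        fitted = qr_red @ (qr_red.T @ y)
        resid = y - fitted

        if fit.stratum[name] == "between":
            n_arrangements = math.factorial(n) if n <= 20 else np.inf
            exhaustive = n_arrangements <= spec.n_permutations
            if exhaustive:
                idx = np.array(list(permutations(range(n))))
            else:
                idx = np.argsort(
                    rng.random((spec.n_permutations, n)), axis=1
                )
            y_star = fitted[:, None] + resid[idx.T]
        else:
            n_arrangements = 2.0**n
            exhaustive = n_arrangements <= spec.n_permutations
            if exhaustive:
                signs = _all_sign_vectors(n)
            else:
                signs = 1.0 - 2.0 * rng.integers(
                    0, 2, size=(spec.n_permutations, n)
                )
            y_star = fitted[:, None] + signs.T * resid[:, None]

        rss_full = _rss(qf, y_star)
        rss_red = _rss(qr_red, y_star)
        df2 = fit.df2[fit.stratum[name]]
        with np.errstate(divide="ignore", invalid="ignore"):
            f_star = (rss_red - rss_full) / (rss_full / df2)
        f_obs = fit.f_stats[name]
        thresh = f_obs - _F_TOL * max(1.0, abs(f_obs))
        n_used = y_star.shape[1]
        count = int(np.sum(f_star >= thresh))
        if exhaustive:
            p = count / n_used  # identity permutation is enumerated
        else:
            p = (count + 1) / (n_used + 1)
        rows.append(
            {
                "term": name,
                "stratum": fit.stratum[name],
                "F": f_obs,
                "df1": 1,
                "df2": df2,
                "p_perm": p,
                "n_perm": n_used,
                "exhaustive": exhaustive,
            }
        )
    return PermutationAnovaResult(table=pd.DataFrame(rows), seed=spec.seed)


def two_sample_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int = 9999,
    seed: int = 0,
    alternative: str = "two-sided",
) -> ContrastResult:
    """Permutation test of a mean difference between two independent groups.

    Exhaustive over all C(n_a + n_b, n_a) group assignments when that count
    does not exceed ``n_permutations`` (exact p, no +1 correction);
    otherwise Monte-Carlo with p = (count + 1) / (B + 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    na, n = a.size, pooled.size
    obs = a.mean() - b.mean()

    def extremity(d):
        if alternative == "two-sided":
            return np.abs(d) >= abs(obs) - _F_TOL * max(1.0, abs(obs))
        if alternative == "greater":
            return d >= obs - _F_TOL * max(1.0, abs(obs))
        if alternative == "less":
            return d <= obs + _F_TOL * max(1.0, abs(obs))
        raise InvalidInputError(f"unknown alternative {alternative!r}")

    total = math.comb(n, na)
    csum = pooled.sum()
    if total <= n_permutations:
        diffs = np.empty(total)
        for i, combo in enumerate(combinations(range(n), na)):
            sa = pooled[list(combo)].sum()
            diffs[i] = sa / na - (csum - sa) / (n - na)
        p = float(np.mean(extremity(diffs)))
        return ContrastResult(
            description="two-sample mean difference",
            estimate=float(obs),
            p_perm=p,
            n_permutations=total,
            exhaustive=True,
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :na]
    sa = pooled[idx].sum(axis=1)
    diffs = sa / na - (csum - sa) / (n - na)
    p = (int(np.sum(extremity(diffs))) + 1) / (n_permutations + 1)
    return ContrastResult(
        description="two-sample mean difference",
        estimate=float(obs),
        p_perm=float(p),
        n_permutations=n_permutations,
        exhaustive=False,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# post hoc marginal means


def marginal_means_contrast(
    data: pd.DataFrame,
    spec: ModelSpec,
    factor: str,
    level_a,
    level_b,
    conditioning: dict | None = None,
    n_permutations: int | None = None,
    seed: int | None = None,
) -> ContrastResult:
    """Difference of marginal means between two levels of one factor.

    Marginal means average the cell means of the full 2^4 design over every
    factor that is neither contrasted nor fixed by ``conditioning`` (e.g.
    short vs long day at the cold test temperature averages over thyroid
    status and acclimation temperature). The permutation p-value reassigns
    the contrasted factor at the level it is randomised: whole-fish label
    permutations within strata of the other between factors for a between
    factor, per-fish label swaps for the within factor.
    """
    conditioning = dict(conditioning or {})
    n_perm = spec.n_permutations if n_permutations is None else n_permutations
    seed = spec.seed if seed is None else seed
    if factor in conditioning:
        raise InvalidInputError(f"cannot condition on the contrasted factor {factor!r}")
    for lvl in (level_a, level_b):
        if lvl not in LEVELS[factor]:
            raise InvalidInputError(f"unknown level {lvl!r} of factor {factor!r}")
    for f, lvl in conditioning.items():
        if lvl not in LEVELS[f]:
            raise InvalidInputError(f"unknown level {lvl!r} of factor {f!r}")

    per_fish, _, _ = _decompose(data, spec)
    d = data.sort_values([spec.subject, spec.within], kind="mergesort")
    y2 = (
        pd.to_numeric(d[spec.response], errors="raise")
        .to_numpy(dtype=float)
        .reshape(len(per_fish), 2)
    )  # columns ordered by within level (sorted)
    within_levels = sorted(LEVELS[spec.within], key=str)

    other_between = [f for f in spec.between if f != factor]
    strat = np.zeros(len(per_fish), dtype=int)
    for f in other_between:
        strat = strat * 2 + (
            per_fish[f].map(lambda l: l == LEVELS[f][1]).to_numpy(dtype=int)
        )

    if factor == spec.within:
        fac_idx = {lvl: i for i, lvl in enumerate(within_levels)}
        swap0 = np.zeros(len(per_fish), dtype=int)

        def contrast(swap):
            ya = np.where(swap == 0, y2[:, fac_idx[level_a]], y2[:, 1 - fac_idx[level_a]])
            yb = np.where(swap == 0, y2[:, fac_idx[level_b]], y2[:, 1 - fac_idx[level_b]])
            return _cell_avg_diff(ya, yb, per_fish, conditioning, strat, other_between)

        obs = contrast(swap0)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            if abs(contrast(rng.integers(0, 2, len(per_fish)))) >= abs(obs) - _F_TOL:
                count += 1
        p = (count + 1) / (n_perm + 1)
    else:
        codes = per_fish[factor].to_numpy()

        def contrast(lab):
            da = _cells_for(lab, level_a, per_fish, conditioning, strat, y2,
                            within_levels, spec)
            db = _cells_for(lab, level_b, per_fish, conditioning, strat, y2,
                            within_levels, spec)
            return da - db

        obs = contrast(codes)
        rng = np.random.default_rng(seed)
        count = 0
        lab = codes.copy()
        for _ in range(n_perm):
            for s in np.unique(strat):
                sel = strat == s
                lab[sel] = rng.permutation(codes[sel])
            if abs(contrast(lab)) >= abs(obs) - _F_TOL:
                count += 1
        p = (count + 1) / (n_perm + 1)

    cond_str = ", ".join(f"{f}={l}" for f, l in conditioning.items()) or "all levels"
    return ContrastResult(
        description=f"{factor}: {level_a} - {level_b} at {cond_str}",
        estimate=float(obs),
        p_perm=float(p),
        n_permutations=n_perm,
        exhaustive=False,
        seed=seed,
    )


def _cell_avg_diff(ya, yb, per_fish, conditioning, strat, other_between):
    """Within-factor contrast: average over (conditioned) between cells of
    cell-mean differences."""
    keep = np.ones(len(per_fish), dtype=bool)
    for f, lvl in conditioning.items():
        keep &= (per_fish[f] == lvl).to_numpy()
    if not keep.any():
        raise AliasingError(f"no subjects satisfy conditioning {conditioning}")
    cells = np.unique(strat[keep])
    da = np.array([ya[keep & (strat == s)].mean() for s in cells])
    db = np.array([yb[keep & (strat == s)].mean() for s in cells])
    return float(np.mean(da - db))


def _cells_for(lab, level, per_fish, conditioning, strat, y2, within_levels, spec):
    """Marginal mean for one level of a between factor given labels ``lab``."""
    keep = lab == level
    for f, lvl in conditioning.items():
        if f == spec.within:
            continue
        keep = keep & (per_fish[f] == lvl).to_numpy()
    if not keep.any():
        raise AliasingError(
            f"empty cell for level {level!r} under conditioning {conditioning}"
        )
    if spec.within in conditioning:
        wcol = within_levels.index(conditioning[spec.within])
        yv = y2[:, wcol]
        cols = [wcol]
    else:
        yv = y2.mean(axis=1)
        cols = None
    cells = np.unique(strat[keep])
    means = [yv[keep & (strat == s)].mean() for s in cells]
    return float(np.mean(means))


# ---------------------------------------------------------------------------
# effect sizes


def _pooled_d(a: np.ndarray, b: np.ndarray, axis: int = -1) -> np.ndarray:
    na = a.shape[axis]
    nb = b.shape[axis]
    va = np.var(a, ddof=1, axis=axis)
    vb = np.var(b, ddof=1, axis=axis)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    # degenerate bootstrap resamples (all-equal values) yield inf, which
    # lands in the extreme tail and leaves percentile ranks sensible
    with np.errstate(divide="ignore", invalid="ignore"):
        return (np.mean(a, axis=axis) - np.mean(b, axis=axis)) / sp


def cohens_d(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    ci_method: str = "bca",
    seed: int = 0,
    description: str = "a - b",
) -> EffectSizeResult:
    """Cohen's d (pooled SD, n−1 weights) with a bootstrap 95% CI.

    Groups are resampled independently. ``ci_method`` is 'bca' (default;
    bias-corrected and accelerated) or 'percentile'. Orient the sign by
    argument order: d > 0 means group_a exceeds group_b.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UndefinedEffectError(
            f"need >= 2 observations per group, got {a.size} and {b.size}"
        )
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if (a.size - 1) * va + (b.size - 1) * vb == 0:
        raise UndefinedEffectError("zero pooled variance: effect size undefined")
    d_obs = float(_pooled_d(a, b))
    method = {"bca": "BCa", "percentile": "percentile"}.get(ci_method)
    if method is None:
        raise InvalidInputError(f"unknown ci_method {ci_method!r}")
    with np.errstate(invalid="ignore"):
        res = stats.bootstrap(
            (a, b),
            _pooled_d,
            n_resamples=n_boot,
            confidence_level=0.95,
            method=method,
            vectorized=True,
            rng=np.random.default_rng(seed),
        )
    return EffectSizeResult(
        description=description,
        cohens_d=d_obs,
        ci_low=float(res.confidence_interval.low),
        ci_high=float(res.confidence_interval.high),
        n_a=a.size,
        n_b=b.size,
        n_boot=n_boot,
        ci_method=ci_method,
        seed=seed,
    )


def thyroid_effect_size(
    data: pd.DataFrame,
    response: str,
    conditioning: dict | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    ci_method: str = "bca",
    seed: int = 0,
) -> EffectSizeResult:
    """Effect of thyroid hormone on a response, optionally within cells.

    Positive d indicates a positive effect of thyroid hormone (normothyroid
    minus hypothyroid).
    """
    d = data
    for f, lvl in (conditioning or {}).items():
        d = d[d[f] == lvl]
    a = d.loc[d["thyroid"] == "normo", response].to_numpy(dtype=float)
    b = d.loc[d["thyroid"] == "hypo", response].to_numpy(dtype=float)
    cond = ", ".join(f"{f}={l}" for f, l in (conditioning or {}).items())
    return cohens_d(
        a,
        b,
        n_boot=n_boot,
        ci_method=ci_method,
        seed=seed,
        description=f"thyroid hormone effect on {response}" + (f" at {cond}" if cond else ""),
    )


def mismatch_effect_size(
    data: pd.DataFrame,
    response: str,
    n_boot: int = DEFAULT_N_BOOT,
    ci_method: str = "bca",
    seed: int = 0,
) -> EffectSizeResult:
    """Warming-mismatch effect: warm conditions on short vs long days.

    Compares the cell with 28 degC acclimation and test temperatures under
    short days (the warming scenario: warm water, winter photoperiod) to
    the same warm cell under long days (natural summer). d > 0 means the
    mismatch increases the response.
    """
    warm = data[(data["acclimation_temp"] == 28) & (data["test_temp"] == 28)]
    a = warm.loc[warm["day_length"] == "short", response].to_numpy(dtype=float)
    b = warm.loc[warm["day_length"] == "long", response].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise MissingPairError(
            f"empty warm-condition cell for response {response!r} "
            f"(short n={a.size}, long n={b.size})"
        )
    return cohens_d(
        a,
        b,
        n_boot=n_boot,
        ci_method=ci_method,
        seed=seed,
        description=f"warm mismatch (short - long day) effect on {response}",
    )
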