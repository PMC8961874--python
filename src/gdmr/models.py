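"""Mixed linear models for GDMR and CBC phenotypes.

Four repeated-measures models are pre-specified, all with a per-animal
random intercept and i.i.d. residuals:

* ``blood``          : response ~ date + breed + sex           (longitudinal blood)
* ``blood_cbc``      : response ~ neutrophils + breed + sex    (count covariate)
* ``somatic``        : response ~ tissue + sex + tissue:sex    (shared tissues)
* ``reproductive``   : response ~ breed + tissue               (sex-specific tissues)

Fitting is REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM`.
On top of the fit this module provides:

* per-term F tests with denominator df ``n_obs - rank(X) - (n_subjects - 1)``
  (a containment-style residual df; Satterthwaite/Kenward-Roger corrections
  are out of scope and would move p-values only marginally at these sizes);
* least-squares means — the estimated marginal mean of each factor level,
  averaging uniformly over the levels of every other factor and holding
  covariates at their sample mean — with SEs from the coefficient covariance;
* Tukey-Kramer all-pairwise comparisons on the LSMeans, summarised as a
  compact letter display (levels sharing no letter differ at ``alpha``);
* BIC model comparison in the SAS MIXED REML convention,
  ``-2 * llf + k_cov * ln(n_subjects)``, penalising the covariance
  parameters only (a ``convention="all"`` flag switches to the textbook
  all-parameters count with N = n_obs);
* significance-gated backward elimination of fixed effects (drop the least
  significant term with p >= alpha, interactions before their main effects,
  refit until all retained terms have p < alpha).

Fixed effects use reference-cell (treatment) coding internally; LSMeans and
their contrasts are the reported, coding-independent quantities.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.formula.api as smf


class ModelSpecError(ValueError):
    pass


class RankDeficiencyError(ValueError):
    """Fixed-effect design matrix is rank deficient; names aliased columns."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed model.

    ``factors`` are categorical fixed effects, ``interactions`` are
    ``"f1:f2"`` pairs of declared factors, ``covariates`` are numeric fixed
    effects, and ``groups`` names the random-intercept grouping column
    (the animal).
    """

    response: str
    factors: tuple[str, ...]
    interactions: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    groups: str = "animal"
    name: str = ""

    def __post_init__(self) -> None:
        for inter in self.interactions:
            parts = inter.split(":")
            if len(parts) != 2 or any(p not in self.factors for p in parts):
                raise ModelSpecError(
                    f"interaction {inter!r} must pair two declared factors {self.factors}"
                )

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.factors) + tuple(self.covariates) + tuple(self.interactions)

    @property
    def formula(self) -> str:
        rhs = [f"C({f})" for f in self.factors]
        rhs += list(self.covariates)
        for inter in self.interactions:
            a, b = inter.split(":")
            rhs.append(f"C({a}):C({b})")
        return f"{self.response} ~ " + (" + ".join(rhs) if rhs else "1")

    def _patsy_term(self, term: str) -> str:
        if term in self.covariates:
            return term
        if ":" in term:
            a, b = term.split(":")
            return f"C({a}):C({b})"
        return f"C({term})"


#: The four pre-specified models (response defaults to blood/tissue GDMR; use
#: ``replace(spec, response=...)`` for CBC components).
MODEL_SPECS: dict[str, ModelSpec] = {
    "blood": ModelSpec("gdmr", ("date", "breed", "sex"), name="blood"),
    "blood_cbc": ModelSpec(
        "gdmr", ("breed", "sex"), covariates=("neutrophils",), name="blood_cbc"
    ),
    "somatic": ModelSpec(
        "gdmr", ("tissue", "sex"), interactions=("tissue:sex",), name="somatic"
    ),
    "reproductive": ModelSpec("gdmr", ("breed", "tissue"), name="reproductive"),
}


@dataclass
class ModelFit:
    """REML fit artifacts for one :class:`ModelSpec` on one table."""

    spec: ModelSpec
    params: pd.Series
    cov_params: pd.DataFrame
    sigma_a2: float
    sigma_e2: float
    loglik: float  # REML log-likelihood
    n_obs: int
    n_subjects: int
    resid_df: int
    anova: pd.DataFrame  # term, F, df_num, df_den, p
    design_info: object
    factor_levels: dict[str, list[str]]
    covariate_means: dict[str, float]
    response_values: np.ndarray = field(repr=False)
    converged: bool = True

    def bic(self, convention: str = "sas") -> float:
        """BIC; ``"sas"`` penalises the 2 covariance parameters with
        N = subjects (MIXED REML convention), ``"all"`` counts every
        parameter with N = observations."""
        if convention == "sas":
            k = 2.0
            n = self.n_subjects
        elif convention == "all":
            k = len(self.params) + 2.0
            n = self.n_obs
        else:
            raise ValueError("convention must be 'sas' or 'all'")
        return -2.0 * self.loglik + k * np.log(n)

    def term_p(self, term: str) -> float:
        row = self.anova.loc[self.anova["term"] == term]
        if row.empty:
            raise KeyError(f"term {term!r} not in fitted model")
        return float(row["p"].iloc[0])


def fit_mixed(table: pd.DataFrame, spec: ModelSpec, *, reml: bool = True) -> ModelFit:
    """Fit one mixed model by REML.

    Rows are deterministically re-sorted before fitting, so estimates are
    exactly invariant to input row order.  Degenerate random-intercept
    designs (< 2 observations for every subject) are refused.
    """
    needed = [spec.response, spec.groups, *spec.factors, *spec.covariates]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ModelSpecError(f"table lacks columns: {missing}")
    data = table[needed].copy()
    if not pd.api.types.is_numeric_dtype(data[spec.response]):
        raise ModelSpecError(f"response {spec.response!r} must be numeric")
    data = data.sort_values(needed, kind="mergesort").reset_index(drop=True)

    counts = data[spec.groups].value_counts()
    if (counts < 2).all():
        raise ModelSpecError(
            "random intercept unidentified: every subject has a single observation"
        )

    # rank check with explicit aliased-column naming
    exog = patsy.dmatrix(spec.formula.split("~", 1)[1], data, return_type="dataframe")
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        _, r = np.linalg.qr(exog.to_numpy())
        aliased = [exog.columns[j] for j in range(r.shape[1]) if abs(r[j, j]) < 1e-8]
        raise RankDeficiencyError(f"aliased fixed-effect columns: {aliased}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(spec.formula, data, groups=data[spec.groups])
        result = None
        for method in (None, "powell", "cg"):
            try:
                kwargs = {} if method is None else {"method": method}
                result = model.fit(reml=reml, **kwargs)
                break
            except np.linalg.LinAlgError:
                continue
        if result is None:
            raise np.linalg.LinAlgError("mixed-model optimisation failed")

    design_info = result.model.data.design_info
    params = result.fe_params
    cov = pd.DataFrame(
        np.asarray(result.cov_params())[: len(params), : len(params)],
        index=params.index,
        columns=params.index,
    )
    n_obs = len(data)
    n_subjects = data[spec.groups].nunique()
    resid_df = n_obs - rank - (n_subjects - 1)
    sigma_a2 = float(np.asarray(result.cov_re)[0, 0])
    sigma_e2 = float(result.scale)

    anova = _term_tests(spec, design_info, params, cov, resid_df)
    levels = {
        f: sorted(pd.unique(data[f].astype(str)).tolist()) for f in spec.factors
    }
    return ModelFit(
        spec=spec,
        params=params,
        cov_params=cov,
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        loglik=float(result.llf),
        n_obs=n_obs,
        n_subjects=n_subjects,
        resid_df=resid_df,
        anova=anova,
        design_info=design_info,
        factor_levels=levels,
        covariate_means={c: float(data[c].mean()) for c in spec.covariates},
        response_values=data[spec.response].to_numpy(),
        converged=bool(getattr(result, "converged", True)),
    )


def _term_tests(
    spec: ModelSpec,
    design_info,
    params: pd.Series,
    cov: pd.DataFrame,
    resid_df: int,
) -> pd.DataFrame:
    """Wald F test for each model term against the residual df."""
    rows = []
    slices = design_info.term_name_slices
    beta = params.to_numpy()
    covm = cov.to_numpy()
    for term in spec.terms:
        patsy_name = spec._patsy_term(term)
        if patsy_name not in slices:
            continue
        sl = slices[patsy_name]
        b = beta[sl]
        v = covm[sl, sl.start : sl.stop]
        q = len(b)
        chi2 = float(b @ np.linalg.solve(v, b))
        fstat = chi2 / q
        p = float(stats.f.sf(fstat, q, resid_df))
        rows.append({"term": term, "F": fstat, "df_num": q, "df_den": resid_df, "p": p})
    return pd.DataFrame(rows, columns=["term", "F", "df_num", "df_den", "p"])


def _lsmean_contrasts(fit: ModelFit, factor: str) -> tuple[list[str], np.ndarray]:
    """Contrast matrix C (levels x coefficients) with LSMeans = C @ beta.

    Row for level l: the design row averaged over the full cross of the
    other factors' levels (uniform weights) with covariates at their sample
    means — the textbook estimated-marginal-means contrast.
    """
    if factor not in fit.spec.factors:
        raise ModelSpecError(f"factor {factor!r} not in model {fit.spec.terms}")
    others = [f for f in fit.spec.factors if f != factor]
    levels = fit.factor_levels[factor]
    contrasts = []
    for level in levels:
        combos = list(itertools.product(*(fit.factor_levels[f] for f in others)))
        grid = pd.DataFrame(
            [
                {factor: level, **dict(zip(others, combo)), **fit.covariate_means}
                for combo in (combos or [()])
            ]
        )
        (X,) = patsy.build_design_matrices([fit.design_info], grid)
        contrasts.append(np.asarray(X).mean(axis=0))
    return levels, np.vstack(contrasts)


def lsmeans(fit: ModelFit, factor: str) -> pd.DataFrame:
    """Least-squares means of one factor: columns level, lsmean, se."""
    levels, C = _lsmean_contrasts(fit, factor)
    beta = fit.params.to_numpy()
    covm = fit.cov_params.to_numpy()
    est = C @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", C, covm, C))
    return pd.DataFrame({"level": levels, "lsmean": est, "se": se})


def tukey(fit: ModelFit, factor: str, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons of a factor's LSMeans.

    The studentized-range statistic for a pair is
    ``q = sqrt(2) * |diff| / se(diff)`` referred to the studentized range
    distribution with ``k`` groups and the fit's residual df; se(diff) comes
    from the full coefficient covariance (Kramer's adjustment for
    unbalanced designs is implicit in the contrast covariance).
    """
    levels, C = _lsmean_contrasts(fit, factor)
    beta = fit.params.to_numpy()
    covm = fit.cov_params.to_numpy()
    est = C @ beta
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = C[i] - C[j]
            diff = est[i] - est[j]
            se = float(np.sqrt(max(c @ covm @ c, 0.0)))
            # zero-variance fits leave se (and diff) at round-off level;
            # compare on a relative scale rather than divide noise by noise
            eps = 1e-10 * (1.0 + abs(est[i]) + abs(est[j]))
            if se > eps:
                q = np.sqrt(2.0) * abs(diff) / se
            else:
                q = 0.0 if abs(diff) <= eps else np.inf
            p = float(stats.studentized_range.sf(q, k, fit.resid_df)) if k > 1 else 1.0
            rows.append(
                {
                    "level_1": levels[i],
                    "level_2": levels[j],
                    "diff": diff,
                    "se": se,
                    "q": q,
                    "p_adj": min(1.0, p),
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def compact_letters(
    levels: list[str], significant: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Two levels share at least one letter iff their pairwise comparison is
    not significant.  ``significant`` maps unordered pairs to booleans.
    """
    groups: list[set[str]] = [set(levels)]
    for (a, b), sig in significant.items():
        if not sig:
            continue
        for g in [g for g in groups if a in g and b in g]:
            groups.remove(g)
            groups.extend([g - {a}, g - {b}])
        # absorb: drop groups contained in another
        groups = [
            g
            for g in groups
            if g and not any(g < h for h in groups if h is not g)
        ]
        # dedupe
        unique: list[set[str]] = []
        for g in groups:
            if g not in unique:
                unique.append(g)
        groups = unique
    # letter assignment ordered by the smallest level index in each group
    order = {lvl: i for i, lvl in enumerate(levels)}
    groups.sort(key=lambda g: min(order[x] for x in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, str] = {lvl: "" for lvl in levels}
    for letter, g in zip(alphabet, groups):
        for lvl in g:
            letters[lvl] += letter
    return {lvl: "".join(sorted(s)) for lvl, s in letters.items()}


def tukey_letters(
    fit: ModelFit, factor: str, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LSMeans table with Tukey letter groupings, plus the pairwise table.

    Levels are lettered in ascending LSMean order (the smallest mean gets
    'a'), matching the usual presentation of such tables.
    """
    ls = lsmeans(fit, factor)
    pairs = tukey(fit, factor, alpha)
    sig = {
        (r.level_1, r.level_2): bool(r.significant) for r in pairs.itertuples()
    }
    by_mean = ls.sort_values("lsmean")["level"].tolist()
    sig_ordered = {
        (a, b): sig.get((a, b), sig.get((b, a), False))
        for a, b in itertools.combinations(by_mean, 2)
    }
    letters = compact_letters(by_mean, sig_ordered)
    ls = ls.assign(letters=[letters[lvl] for lvl in ls["level"]])
    return ls, pairs


class BICComparisonError(ValueError):
    pass


def compare_bic(fits: list[ModelFit], convention: str = "sas") -> pd.DataFrame:
    """Rank fits by ascending BIC.

    All fits must be on the identical response records; fits whose fixed
    effects differ are flagged with the REML-comparison caveat (REML
    likelihoods of different mean structures are not strictly comparable —
    the published model comparison did exactly this, so the ranking is
    still reported).
    """
    if not fits:
        raise BICComparisonError("no fits to compare")
    ref = fits[0].response_values
    for f in fits[1:]:
        if len(f.response_values) != len(ref) or not np.allclose(
            np.sort(f.response_values), np.sort(ref)
        ):
            raise BICComparisonError("fits are not on identical response records")
    same_fixed = len({f.spec.terms for f in fits}) == 1
    rows = [
        {
            "model": f.spec.name or f.spec.formula,
            "bic": f.bic(convention),
            "loglik": f.loglik,
            "n_subjects": f.n_subjects,
            "caveat": "" if same_fixed else "REML-comparison",
        }
        for f in fits
    ]
    out = pd.DataFrame(rows).sort_values("bic", kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def retain_effects(
    table: pd.DataFrame,
    response: str,
    factors: tuple[str, ...] = (),
    interactions: tuple[str, ...] = (),
    covariates: tuple[str, ...] = (),
    *,
    groups: str = "animal",
    alpha: float = 0.05,
) -> ModelSpec:
    """Backward elimination: keep only fixed effects with p < alpha.

    Repeatedly drops the least significant removable term (p >= alpha);
    interactions are removable before the main effects they contain, ties
    break toward the higher-order term and then lexicographically.  Returns
    the retained :class:`ModelSpec` (possibly intercept-only).
    """
    cur_factors = list(factors)
    cur_inters = list(interactions)
    cur_covs = list(covariates)
    while cur_factors or cur_inters or cur_covs:
        spec = ModelSpec(
            response,
            tuple(cur_factors),
            tuple(cur_inters),
            tuple(cur_covs),
            groups=groups,
        )
        fit = fit_mixed(table, spec)
        in_interaction = {p for inter in cur_inters for p in inter.split(":")}
        candidates = []
        for term in spec.terms:
            p = fit.term_p(term)
            if p < alpha:
                continue
            is_inter = ":" in term
            if not is_inter and term in in_interaction:
                continue  # main effect protected by its interaction
            candidates.append((p, 0 if is_inter else 1, term))
        if not candidates:
            return spec
        candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
        drop = candidates[0][2]
        if ":" in drop:
            cur_inters.remove(drop)
        elif drop in cur_covs:
            cur_covs.remove(drop)
        else:
            cur_factors.remove(drop)
    return ModelSpec(response, (), (), (), groups=groups)
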