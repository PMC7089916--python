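"""What makes dyads preferred associates: ranks, covariates, multimodel inference.

This module covers the second analysis level: dominance ranks from feeding
supplants (sequential Elo, standardized ordinal ranks), construction of the
dyad-year covariate table (kinship, sex/age/infant combinations, rank
difference), regression of the significant-associate flag (binomial) and of
the PAV (gaussian) on those covariates, and information-theoretic multimodel
inference — all-subsets enumeration under marginality, AICc, Akaike weights,
the 95% best-model confidence set, summed predictor weights — together with
dyad-flip resampling, VIF collinearity screening, Nakagawa-style R² and a
leave-one-level-out influence check.

Model estimation is delegated to statsmodels.  The default engine fits
fixed-effects GLMs, the correct likelihood when random-effect variance is
zero (as in the synthetic fixtures) and the basis for all AICc machinery; a
gaussian mixed engine (variance components for both individuals, the dyad
and the year via ``MixedLM``) is available for variance decomposition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

# terms of the full model; interactions use ':' and obey marginality
TERM_KINSHIP = "kinship"
TERM_RANK = "rank_diff"
TERM_SEX = "sex_combo"
TERM_AGE = "age_combo"
TERM_INFANT = "infant_combo"
TERM_SEX_RANK = "sex_combo:rank_diff"
TERM_SEX_AGE = "sex_combo:age_combo"

FULL_MODEL = frozenset(
    {TERM_KINSHIP, TERM_RANK, TERM_SEX, TERM_AGE, TERM_INFANT, TERM_SEX_RANK, TERM_SEX_AGE}
)

REFERENCE_LEVELS = {
    TERM_SEX: "female_female",
    TERM_AGE: "adult_adult",
    TERM_INFANT: "no_no",
}

_PATSY = {
    TERM_KINSHIP: "kinship",
    TERM_RANK: "rank_diff_z",
    TERM_SEX: "C(sex_combo, Treatment('female_female'))",
    TERM_AGE: "C(age_combo, Treatment('adult_adult'))",
    TERM_INFANT: "C(infant_combo, Treatment('no_no'))",
}


# ---------------------------------------------------------------------------
# Elo ratings and standardized ranks
# ---------------------------------------------------------------------------


@dataclass
class EloState:
    """Sequential Elo ratings with the per-interaction trajectory.

    Winner gains ``k * (1 - p_expected)`` and the loser loses the same
    amount, with the win expectation logistic in the rating difference
    (base-10 over ``scale`` points, the classical parameterization).  The
    total rating is conserved by every update.
    """

    ratings: dict
    k_factor: float
    initial: float
    scale: float
    history: pd.DataFrame  # date, winner, loser, expected, winner_rating, loser_rating


def elo_ratings(
    supplants: pd.DataFrame,
    k_factor: float = 16.0,
    initial: float = 1000.0,
    scale: float = 400.0,
    individuals: Iterable[str] | None = None,
) -> EloState:
    """Sequential Elo over chronologically sorted supplant records.

    ``supplants`` needs columns ``date, winner, loser``.  ``individuals``
    restricts the legal ids; unknown ids raise.
    """
    df = supplants.sort_values("date", kind="stable").reset_index(drop=True)
    known = set(individuals) if individuals is not None else None
    ratings: dict = {}
    rows = []
    for _, rec in df.iterrows():
        w, l = rec["winner"], rec["loser"]
        if w == l:
            raise ValueError(f"supplant on {rec['date']}: winner equals loser ({w})")
        for who in (w, l):
            if known is not None and who not in known:
                raise KeyError(f"supplant on {rec['date']}: unknown individual {who!r}")
            ratings.setdefault(who, initial)
        exp_w = 1.0 / (1.0 + 10.0 ** ((ratings[l] - ratings[w]) / scale))
        delta = k_factor * (1.0 - exp_w)
        ratings[w] += delta
        ratings[l] -= delta
        rows.append((rec["date"], w, l, exp_w, ratings[w], ratings[l]))
    history = pd.DataFrame(rows, columns=["date", "winner", "loser", "expected", "winner_rating", "loser_rating"])
    return EloState(ratings=ratings, k_factor=k_factor, initial=initial, scale=scale, history=history)


def standardized_ordinal_rank(ratings: Mapping[str, float]) -> dict:
    """Map ratings to standardized ordinal ranks on [0, 1] (top = 1).

    Linear in ordinal position; rating ties share the mean ordinal
    position; a single individual scores 1.0 by convention.
    """
    ids = list(ratings)
    n = len(ids)
    if n == 0:
        return {}
    if n == 1:
        return {ids[0]: 1.0}
    r = scipy.stats.rankdata([ratings[i] for i in ids], method="average")  # 1 = lowest
    return {i: (rv - 1.0) / (n - 1.0) for i, rv in zip(ids, r)}


def daily_standardized_ranks(
    supplants: pd.DataFrame,
    k_factor: float = 16.0,
    initial: float = 1000.0,
    scale: float = 400.0,
    individuals: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Standardized ordinal ranks at the end of each interaction day.

    Returns a long DataFrame ``date, id, rank`` covering every individual
    rated so far on each day with at least one supplant.
    """
    state = elo_ratings(supplants, k_factor, initial, scale, individuals)
    df = supplants.sort_values("date", kind="stable")
    ratings: dict = {}
    rows = []
    hist = state.history
    for date, day in hist.groupby("date", sort=True):
        for _, rec in day.iterrows():
            ratings[rec["winner"]] = rec["winner_rating"]
            ratings[rec["loser"]] = rec["loser_rating"]
        for i, rv in standardized_ordinal_rank(ratings).items():
            rows.append((date, i, rv))
    return pd.DataFrame(rows, columns=["date", "id", "rank"])


def yearly_rank(daily: pd.DataFrame) -> dict:
    """Season rank per individual: arithmetic mean of daily values."""
    if daily.empty:
        raise ValueError("no daily rank values")
    return daily.groupby("id")["rank"].mean().to_dict()


# ---------------------------------------------------------------------------
# Dyad-year covariate table
# ---------------------------------------------------------------------------


def _combo(x: str, y: str, order: Sequence[str]) -> str:
    a, b = sorted((x, y), key=order.index)
    return f"{a}_{b}"


def is_kin(a, b) -> bool:
    """Maternal kin: mother-offspring pair or maternal siblings."""
    if a.mother_id is not None and a.mother_id == b.id:
        return True
    if b.mother_id is not None and b.mother_id == a.id:
        return True
    return a.mother_id is not None and a.mother_id == b.mother_id


def build_dyad_rows(
    dyad_tables: Mapping[str, pd.DataFrame],
    rosters: Mapping[str, "SeasonRoster"],
    ranks: Mapping[str, Mapping[str, float]],
    z_standardize: bool = True,
) -> pd.DataFrame:
    """One covariate row per dyad per season, pooled across seasons.

    ``dyad_tables`` maps season label to the per-season association table
    (from :func:`assocpat.dyadic_association.dyad_table`); ``ranks`` maps
    season to yearly mean standardized ranks.  The rank difference is the
    absolute difference of the two members' yearly ranks, z-standardized
    across the pooled table when requested (raw values are kept in
    ``rank_diff``).  Reference levels: female_female, adult_adult, no_no.
    """
    frames = []
    for season, table in dyad_tables.items():
        roster = rosters[season]
        season_ranks = ranks[season]
        rows = []
        for _, rec in table.iterrows():
            ia, ib = rec["id_a"], rec["id_b"]
            a, b = roster[ia], roster[ib]
            for ind in (a, b):
                if ind.id not in season_ranks:
                    raise ValueError(f"season {season}: no rank for individual {ind.id!r}")
            rows.append(
                {
                    "dyad": f"{min(ia, ib)}|{max(ia, ib)}",
                    "season": season,
                    "id_1": min(ia, ib),
                    "id_2": max(ia, ib),
                    "response_sig": int(bool(rec["significant"])),
                    "response_pav": float(rec["pav"]),
                    "kinship": int(is_kin(a, b)),
                    "rank_diff": abs(season_ranks[ia] - season_ranks[ib]),
                    "sex_combo": _combo(a.sex, b.sex, ("female", "male")),
                    "age_combo": _combo(
                        roster.age_class_of(ia), roster.age_class_of(ib), ("adult", "subadult")
                    ),
                    "infant_combo": _combo(
                        "yes" if roster.has_infant(ia) else "no",
                        "yes" if roster.has_infant(ib) else "no",
                        ("yes", "no"),
                    ),
                }
            )
        frames.append(pd.DataFrame(rows))
    out = pd.concat(frames, ignore_index=True)
    if z_standardize and out["rank_diff"].std() > 0:
        out["rank_diff_z"] = (out["rank_diff"] - out["rank_diff"].mean()) / out["rank_diff"].std()
    else:
        out["rank_diff_z"] = out["rank_diff"] - out["rank_diff"].mean()
    return out


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    spec: frozenset
    family: str
    engine: str
    params: pd.Series
    bse: pd.Series
    loglik: float
    k: int
    n: int
    converged: bool
    linpred_var: float = np.nan
    vc: dict = field(default_factory=dict)
    scale: float = np.nan


def _formula(spec: frozenset, response: str) -> str:
    mains = [t for t in (TERM_KINSHIP, TERM_RANK, TERM_SEX, TERM_AGE, TERM_INFANT) if t in spec]
    terms = [_PATSY[t] for t in mains]
    if TERM_SEX_RANK in spec:
        terms.append(f"{_PATSY[TERM_SEX]}:{_PATSY[TERM_RANK]}")
    if TERM_SEX_AGE in spec:
        terms.append(f"{_PATSY[TERM_SEX]}:{_PATSY[TERM_AGE]}")
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


def fit_model(
    rows: pd.DataFrame,
    spec: frozenset = FULL_MODEL,
    family: str = "binomial",
    engine: str = "fixed",
    response: str | None = None,
) -> FitResult:
    """Fit one submodel of the dyadic association regression.

    ``family`` is ``"binomial"`` (significant-associate flag) or
    ``"gaussian"`` (PAV).  The ``"fixed"`` engine fits a GLM; the
    ``"mixed"`` engine (gaussian only) adds variance components for both
    individual identities, the dyad and the season via ``MixedLM``.  The
    returned ``k`` counts estimated parameters (including the residual
    variance for gaussian models), as AICc requires.
    """
    spec = frozenset(spec)
    _check_marginality(spec)
    if response is None:
        response = "response_sig" if family == "binomial" else "response_pav"
    formula = _formula(spec, response)
    n = len(rows)

    if engine == "fixed":
        fam = sm.families.Binomial() if family == "binomial" else sm.families.Gaussian()
        model = smf.glm(formula, data=rows, family=fam)
        with np.errstate(all="ignore"):
            res = model.fit()
        converged = bool(getattr(res, "converged", True)) and np.isfinite(res.llf)
        k = len(res.params) + (1 if family == "gaussian" else 0)
        return FitResult(
            spec=spec,
            family=family,
            engine=engine,
            params=res.params,
            bse=res.bse,
            loglik=float(res.llf),
            k=k,
            n=n,
            converged=converged,
            linpred_var=float(np.var(res.predict(which="linear") if family == "binomial" else res.fittedvalues)),
            scale=float(res.scale),
        )

    if engine == "mixed":
        if family != "gaussian":
            raise NotImplementedError(
                "mixed engine supports the gaussian family only; use engine='fixed' for binomial"
            )
        vc = {"id1": "0 + C(id_1)", "id2": "0 + C(id_2)", "dyad": "0 + C(dyad)", "year": "0 + C(season)"}
        data = rows.copy()
        data["_one"] = 1
        model = smf.mixedlm(formula, data=data, groups="_one", vc_formula=vc, re_formula="0")
        with np.errstate(all="ignore"):
            res = model.fit(reml=False, method="lbfgs", maxiter=200)
        converged = bool(res.converged) and np.isfinite(res.llf)
        k = len(res.fe_params) + len(vc) + 1
        return FitResult(
            spec=spec,
            family=family,
            engine=engine,
            params=res.fe_params,
            bse=res.bse_fe,
            loglik=float(res.llf),
            k=k,
            n=n,
            converged=converged,
            linpred_var=float(np.var(np.asarray(model.exog) @ np.asarray(res.fe_params))),
            vc={name: float(v) for name, v in res.vcomp_named.items()} if hasattr(res, "vcomp_named") else dict(zip(vc, np.atleast_1d(res.vcomp).tolist())),
            scale=float(res.scale),
        )

    raise ValueError(f"unknown engine {engine!r}")


def _check_marginality(spec: frozenset) -> None:
    for term in spec:
        if ":" in term:
            for parent in term.split(":"):
                if parent not in spec:
                    raise ValueError(f"interaction {term} requires main effect {parent}")


# ---------------------------------------------------------------------------
# All-subsets enumeration and information-theoretic machinery
# ---------------------------------------------------------------------------


def enumerate_submodels(full: frozenset = FULL_MODEL) -> list:
    """Every predictor subset of the full model honoring marginality.

    Includes the intercept-only model; for the study's full model (five
    main effects, two interactions sharing the sex term) this yields 52
    submodels.  Deterministic order (sorted by size, then lexically).
    """
    full = frozenset(full)
    out = []
    terms = sorted(full)
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            s = frozenset(combo)
            try:
                _check_marginality(s)
            except ValueError:
                continue
            out.append(s)
    out.sort(key=lambda s: (len(s), sorted(s)))
    return out


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalized evidence weights from AICc values (location-invariant)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def confidence_set(weights, level: float = 0.95) -> np.ndarray:
    """Indices of the smallest weight-sorted prefix with cumulative weight >= level."""
    w = np.asarray(weights, dtype=float)
    order = np.argsort(-w, kind="stable")
    cum = np.cumsum(w[order])
    cutoff = int(np.searchsorted(cum, level) + 1)
    return order[: min(cutoff, len(w))]


def predictor_weights(specs: Sequence[frozenset], weights) -> pd.DataFrame:
    """Summed Akaike weight per predictor and its equal-performance expectation.

    Expected weight (default definition) is the share of models containing
    the predictor — the summed weight if all models performed equally.
    """
    w = np.asarray(weights, dtype=float)
    terms = sorted({t for s in specs for t in s})
    rows = []
    for t in terms:
        contains = np.array([t in s for s in specs])
        rows.append((t, float(w[contains].sum()), float(contains.mean())))
    return pd.DataFrame(rows, columns=["term", "summed_weight", "expected_weight"])


@dataclass
class MultimodelResult:
    """All-subsets AICc inference for one response family."""

    family: str
    table: pd.DataFrame          # one row per submodel
    specs: list
    weights: np.ndarray
    confidence_idx: np.ndarray
    predictor_weights: pd.DataFrame
    null_in_confidence_set: bool
    full_fit: FitResult
    n_nonconverged: int


def multimodel_inference(
    rows: pd.DataFrame,
    full: frozenset = FULL_MODEL,
    family: str = "binomial",
    engine: str = "fixed",
    level: float = 0.95,
) -> MultimodelResult:
    """Fit all marginality-respecting submodels and weigh the evidence.

    Non-convergent fits are dropped from the weight normalization (count
    logged).  Predictor weights are reported regardless, but the
    ``null_in_confidence_set`` flag marks when the intercept-only model
    sits inside the confidence set, in which case they should not be
    interpreted.
    """
    specs = enumerate_submodels(full)
    fits, kept_specs = [], []
    n_bad = 0
    for s in specs:
        f = fit_model(rows, s, family=family, engine=engine)
        if not f.converged:
            n_bad += 1
            continue
        fits.append(f)
        kept_specs.append(s)
    if n_bad:
        log.info("multimodel_inference: dropped %d non-convergent submodels", n_bad)
    if not fits:
        raise RuntimeError("no submodel converged")

    a = np.array([aicc(f.loglik, f.k, f.n) for f in fits])
    w = akaike_weights(a)
    conf = confidence_set(w, level)
    in_conf = set(conf.tolist())
    null_idx = next((i for i, s in enumerate(kept_specs) if not s), None)
    null_in = null_idx is not None and null_idx in in_conf

    table = pd.DataFrame(
        {
            "terms": [" + ".join(sorted(s)) if s else "(intercept)" for s in kept_specs],
            "n_terms": [len(s) for s in kept_specs],
            "loglik": [f.loglik for f in fits],
            "k": [f.k for f in fits],
            "aicc": a,
            "delta_aicc": a - a.min(),
            "weight": w,
            "in_confidence_set": [i in in_conf for i in range(len(fits))],
        }
    ).sort_values("aicc", kind="stable", ignore_index=True)

    full_fit = next((f for f, s in zip(fits, kept_specs) if s == frozenset(full)), None)
    if full_fit is None:
        full_fit = fit_model(rows, full, family=family, engine=engine)

    return MultimodelResult(
        family=family,
        table=table,
        specs=kept_specs,
        weights=w,
        confidence_idx=conf,
        predictor_weights=predictor_weights(kept_specs, w),
        null_in_confidence_set=null_in,
        full_fit=full_fit,
        n_nonconverged=n_bad,
    )


# ---------------------------------------------------------------------------
# Dyad-flip resampling
# ---------------------------------------------------------------------------


@dataclass
class DyadFlipResult:
    family: str
    n_selections: int
    n_converged: int
    mean_estimates: pd.Series        # full-model coefficients averaged over selections
    mean_summed_weights: pd.DataFrame | None
    predictor_expected: pd.DataFrame | None


def dyad_flip_inference(
    rows: pd.DataFrame,
    full: frozenset = FULL_MODEL,
    family: str = "binomial",
    n_selections: int = 1000,
    seed=None,
    engine: str = "fixed",
    refit_subsets: bool = True,
) -> DyadFlipResult:
    """Average estimates and Akaike weights over random dyad orientations.

    Which member of an unordered dyad occupies the individual-1 versus
    individual-2 slot is arbitrary but, through the random-effects
    structure, not inert; each selection randomly re-orients every dyad
    (consistently across its seasons), refits the full model, and — when
    ``refit_subsets`` — reruns the all-subsets inference.  Means are taken
    over converged selections.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    dyads = rows["dyad"].unique()
    est_sum = None
    weight_sum = None
    expected = None
    n_ok = 0
    for _ in range(n_selections):
        flip = dict(zip(dyads, rng.random(len(dyads)) < 0.5))
        sel = rows.copy()
        mask = sel["dyad"].map(flip)
        sel.loc[mask, ["id_1", "id_2"]] = sel.loc[mask, ["id_2", "id_1"]].to_numpy()

        try:
            if refit_subsets:
                mm = multimodel_inference(sel, full, family=family, engine=engine)
                fit, pw = mm.full_fit, mm.predictor_weights
            else:
                fit = fit_model(sel, full, family=family, engine=engine)
                pw = None
        except Exception as exc:  # non-convergence and numerical failures
            log.warning("dyad-flip selection failed: %s", exc)
            continue
        if not fit.converged:
            continue
        n_ok += 1
        est_sum = fit.params if est_sum is None else est_sum + fit.params
        if pw is not None:
            expected = pw[["term", "expected_weight"]]
            sw = pw.set_index("term")["summed_weight"]
            weight_sum = sw if weight_sum is None else weight_sum + sw
    if n_ok == 0:
        raise RuntimeError("no dyad-flip selection converged")
    if n_ok < n_selections:
        log.info("dyad_flip_inference: %d of %d selections dropped", n_selections - n_ok, n_selections)
    mean_weights = None
    if weight_sum is not None:
        mean_weights = (weight_sum / n_ok).rename("mean_summed_weight").reset_index()
    return DyadFlipResult(
        family=family,
        n_selections=n_selections,
        n_converged=n_ok,
        mean_estimates=est_sum / n_ok,
        mean_summed_weights=mean_weights,
        predictor_expected=expected,
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def vif(rows: pd.DataFrame, predictors: Sequence[str] = (TERM_KINSHIP, TERM_RANK, TERM_SEX, TERM_AGE, TERM_INFANT)) -> pd.DataFrame:
    """Generalized variance inflation factors, interactions excluded.

    Computed from the correlation matrix of the fixed-effects design
    (GVIF = det(R11) det(R22) / det(R), the standard generalization for
    multi-column categorical terms; for a single column this is the
    familiar 1/(1 - R²)).  Also reports GVIF^(1/2df)), the df-adjusted
    scale.  Perfect collinearity yields ``inf``.
    """
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    import patsy

    rhs = " + ".join(_PATSY[t] for t in predictors)
    design = patsy.dmatrix(rhs, rows, return_type="dataframe")
    info = design.design_info
    cols = design.drop(columns="Intercept")
    R = np.corrcoef(cols.to_numpy(), rowvar=False)
    det_all = np.linalg.det(R)
    names = list(cols.columns)
    out = []
    for term, patsy_term in zip(predictors, (_PATSY[t] for t in predictors)):
        sl = info.term_name_slices[patsy_term]
        members = [c for c in design.columns[sl]]
        idx = [names.index(c) for c in members]
        rest = [i for i in range(len(names)) if i not in idx]
        if det_all <= 0:
            g = np.inf
        else:
            g = np.linalg.det(R[np.ix_(idx, idx)]) * np.linalg.det(R[np.ix_(rest, rest)]) / det_all
        df = len(idx)
        out.append((term, float(g), df, float(g) ** (1.0 / (2 * df)) if np.isfinite(g) else np.inf))
    return pd.DataFrame(out, columns=["term", "gvif", "df", "gvif_scaled"])


def r2_mixed(fit) -> tuple:
    """Nakagawa marginal and conditional R² from a fit or variance components.

    Accepts a :class:`FitResult` or a dict with keys ``fixed``, ``random``,
    ``residual``.  For binomial (logit) fits the distribution-specific
    residual variance pi²/3 is used; for the fixed engine the random-effect
    variance is zero, so marginal equals conditional.
    """
    if isinstance(fit, dict):
        vf, vr, ve = fit["fixed"], fit["random"], fit["residual"]
    elif isinstance(fit, FitResult):
        vf = fit.linpred_var
        vr = float(sum(fit.vc.values())) if fit.vc else 0.0
        if fit.family == "binomial":
            ve = np.pi**2 / 3.0
        else:
            ve = fit.scale
    else:
        raise TypeError("expected FitResult or components dict")
    denom = vf + vr + ve
    return vf / denom, (vf + vr) / denom


def influence_check(
    rows: pd.DataFrame,
    spec: frozenset = FULL_MODEL,
    family: str = "binomial",
    factor: str = "id",
    engine: str = "fixed",
) -> pd.DataFrame:
    """Leave-one-level-out refits of a random-effect factor.

    ``factor`` is ``"id"`` (levels = union of both individual slots;
    dropping a level removes every row containing that individual) or
    ``"year"`` (season levels).  Returns the per-level coefficient shifts
    with the maximum absolute shift per coefficient in
    ``.attrs["max_shift"]``.
    """
    if factor == "id":
        levels = sorted(set(rows["id_1"]) | set(rows["id_2"]))
        drop = lambda lv: rows[(rows["id_1"] != lv) & (rows["id_2"] != lv)]
    elif factor == "year":
        levels = sorted(rows["season"].unique())
        drop = lambda lv: rows[rows["season"] != lv]
    else:
        raise ValueError(f"unknown factor {factor!r}")
    if len(levels) < 2:
        raise ValueError(f"cannot remove levels of {factor!r}: only {len(levels)} level(s)")

    base = fit_model(rows, spec, family=family, engine=engine)
    shifts = {}
    for lv in levels:
        sub = drop(lv)
        f = fit_model(sub, spec, family=family, engine=engine)
        shifts[lv] = (f.params - base.params).reindex(base.params.index)
    out = pd.DataFrame(shifts).T
    out.attrs["max_shift"] = out.abs().max().to_dict()
    return out
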