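"""Mixed-model specification, BIC-based simplification, and reporting.

The response is log capture time.  The maximal model carries the design
nuisance terms (log edge distance, first-slide and played-before
indicators, slide number, age bracket), the viewing condition, the
camouflage covariates, and the 2-way interactions of each camouflage
covariate with viewing condition and with slide number; random intercepts
for session, photograph and (optionally) season.  Simplification follows a
three-phase stepwise procedure:

1. backward-eliminate fixed effects under ML, repeatedly dropping the term
   whose removal most decreases BIC (interactions always before their
   parents, so marginality is preserved), starting from a base random
   structure (session intercept);
2. forward-add random intercepts from the allowed set under REML, keeping
   additions that decrease BIC;
3. re-run the backward fixed-effect pass under ML with the final random
   structure.

BIC = -2 logLik + k ln(n) with k = fixed parameters + variance components
+ 1 (residual).  Ties (|dBIC| < 1e-6) resolve toward the smaller model.
Non-converged candidate fits count as "not an improvement".  Wald F
statistics are reported per term with the lower-bound denominator df
convention df = n - (fixed parameters) - (total random-effect levels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from patsy import dmatrices
from scipy import stats

from .mixedlm import LMMResult, RandomInterceptLMM

__all__ = [
    "ModelSpec",
    "FitResult",
    "SelectionStep",
    "SelectionTrace",
    "fit",
    "simplify",
    "report",
    "default_maximal_spec",
    "recovery_maximal_spec",
    "recovery_behavior",
    "recovery_study",
    "RecoveryResult",
]

#: BIC difference below which two models are tied (smaller model preferred)
BIC_TIE_EPS = 1e-6

CAMO_COVARIATES = (
    "log_pattern_diff",
    "lum_dist_diff",
    "target_area",
    "bg_lum_mean",
    "bg_contrast",
    "target_lum_mean",
    "target_contrast",
)

_AGE_ORDER = ("<10", "10-15", "16-35", "36-50", ">50")


@dataclass(frozen=True)
class ModelSpec:
    """A mixed-model specification over analysis-table columns.

    ``fixed_terms`` are column names, 2-way interactions written "a:b", and
    the optional quadratic learning term "I(slide_number ** 2)".
    ``random_terms`` is the candidate set for forward selection;
    ``base_random`` is the mandatory structure every fit carries (the
    session intercept, without which repeated measures within a participant
    would be treated as independent).
    """

    response: str = "log_capture_time"
    fixed_terms: tuple[str, ...] = ()
    random_terms: tuple[str, ...] = ("session_id", "photo_id")
    base_random: tuple[str, ...] = ("session_id",)
    estimation: str = "ML"

    def __post_init__(self) -> None:
        if self.estimation not in ("ML", "REML"):
            raise ValueError("estimation must be 'ML' or 'REML'")
        if not set(self.base_random) <= set(self.random_terms):
            raise ValueError("base_random must be a subset of random_terms")
        if len(self.base_random) == 0:
            raise ValueError("at least one mandatory random term is required")
        for t in self.fixed_terms:
            for parent in term_parents(t):
                if parent not in self.fixed_terms:
                    raise ValueError(
                        f"term {t!r} requires its parent {parent!r} (marginality)"
                    )


def term_parents(term: str) -> tuple[str, ...]:
    """Marginality parents: 'a:b' -> (a, b); quadratic slide -> linear."""
    if ":" in term:
        return tuple(term.split(":"))
    if term == "I(slide_number ** 2)":
        return ("slide_number",)
    return ()


def _map_factor(name: str, table: pd.DataFrame) -> str:
    """Patsy factor expression with the study's reference levels."""
    if name == "viewing_condition":
        return "C(viewing_condition, Treatment('trichromat'))"
    if name == "age_class":
        present = [a for a in _AGE_ORDER if a in set(table["age_class"])]
        ref = present[0] if present else sorted(set(table["age_class"]))[0]
        return f"C(age_class, Treatment({ref!r}))"
    return name

def _formula(spec: ModelSpec, table: pd.DataFrame) -> tuple[str, dict[str, str]]:
    """Build the patsy formula; return it plus term -> patsy-term-name map."""
    mapped: dict[str, str] = {}
    rhs = []
    for t in spec.fixed_terms:
        parts = t.split(":")
        expr = ":".join(_map_factor(p, table) for p in parts)
        mapped[t] = expr
        rhs.append(expr)
    formula = f"{spec.response} ~ 1" + "".join(f" + {e}" for e in rhs)
    return formula, mapped


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(X)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in np.where(d <= tol)[0]]


class _Design:
    """Full design matrix + random-factor codes, sliceable per candidate."""

    def __init__(self, table: pd.DataFrame, spec: ModelSpec):
        formula, self.term_map = _formula(spec, table)
        y_df, x_df = dmatrices(formula, table, return_type="dataframe")
        self.y = np.asarray(y_df).ravel()
        self.X = np.asarray(x_df)
        self.col_names = list(x_df.columns)
        info = x_df.design_info
        self.term_slices: dict[str, slice] = {"Intercept": info.term_name_slices["Intercept"]}
        for t, patsy_name in self.term_map.items():
            self.term_slices[t] = info.term_name_slices[patsy_name]
        if len(self.y) != len(table):
            raise ValueError("missing values in model columns")

        aliased = _aliased_columns(self.X, self.col_names)
        if aliased:
            raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

        self.factors: dict[str, np.ndarray] = {}
        self.factor_levels: dict[str, int] = {}
        for f in spec.random_terms:
            if f not in table.columns:
                raise ValueError(f"random term {f!r} not in table")
            codes = pd.Categorical(table[f]).codes
            self.factors[f] = codes
            self.factor_levels[f] = int(codes.max()) + 1
        self.solver = RandomInterceptLMM(self.y, self.X, self.factors)

    def cols_for(self, terms: tuple[str, ...]) -> np.ndarray:
        idx: list[int] = list(range(*self.term_slices["Intercept"].indices(self.X.shape[1])))
        for t in terms:
            idx.extend(range(*self.term_slices[t].indices(self.X.shape[1])))
        return np.asarray(sorted(idx), dtype=np.intp)

    def names_for(self, cols: np.ndarray) -> list[str]:
        return [self.col_names[i] for i in cols]


@dataclass
class FitResult:
    """A fitted mixed model with per-term Wald F statistics."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    terms: pd.DataFrame  # term, df_num, df_den, F, p
    llf: float
    bic: float
    n: int
    k_params: int
    vc_sd: dict[str, float]
    sigma_resid: float
    converged: bool
    raw: LMMResult = field(repr=False)


def _term_ftable(
    design: _Design,
    terms: tuple[str, ...],
    cols: np.ndarray,
    res: LMMResult,
    fitted_factors: list[str],
) -> pd.DataFrame:
    n_levels = sum(design.factor_levels[f] for f in fitted_factors)
    df_den = res.n - res.p - n_levels
    pos = {c: i for i, c in enumerate(cols)}
    rows = []
    for t in terms:
        sl = design.term_slices[t]
        idx = [pos[c] for c in range(*sl.indices(design.X.shape[1]))]
        b = res.beta[idx]
        cov = res.cov_beta[np.ix_(idx, idx)]
        df_num = len(idx)
        fstat = float(b @ np.linalg.solve(cov, b)) / df_num
        pval = float(stats.f.sf(fstat, df_num, max(df_den, 1)))
        rows.append({"term": t, "df_num": df_num, "df_den": df_den, "F": fstat, "p": pval})
    return pd.DataFrame(rows, columns=["term", "df_num", "df_den", "F", "p"])


def _fit_design(
    design: _Design,
    spec: ModelSpec,
    terms: tuple[str, ...],
    random_terms: tuple[str, ...],
    reml: bool,
    start_lam: np.ndarray | None = None,
) -> FitResult:
    cols = design.cols_for(terms)
    res = design.solver.fit(
        cols=cols, factor_subset=list(random_terms), reml=reml, start_lam=start_lam
    )
    names = design.names_for(cols)
    params = pd.Series(res.beta, index=names)
    bse = pd.Series(res.bse, index=names)
    fitted = replace(
        spec,
        fixed_terms=terms,
        random_terms=random_terms,
        base_random=tuple(t for t in spec.base_random if t in random_terms) or random_terms[:1],
        estimation="REML" if reml else "ML",
    )
    return FitResult(
        spec=fitted,
        params=params,
        bse=bse,
        tvalues=params / bse,
        terms=_term_ftable(design, terms, cols, res, list(random_terms)),
        llf=res.llf,
        bic=res.bic,
        n=res.n,
        k_params=res.k_params,
        vc_sd=res.vc_sd,
        sigma_resid=float(np.sqrt(res.sigma2)),
        converged=res.converged,
        raw=res,
    )


def fit(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one ModelSpec on an analysis table.

    Treatment coding uses trichromat and the lowest age bracket present as
    references.  Raises on rank-deficient designs (listing the aliased
    columns) and on random factors with fewer than 2 levels.
    """
    design = _Design(table, spec)
    use_random = spec.random_terms if spec.random_terms else spec.base_random
    return _fit_design(
        design, spec, spec.fixed_terms, tuple(use_random), reml=spec.estimation == "REML"
    )


@dataclass(frozen=True)
class SelectionStep:
    step: int
    phase: str  # drop-fixed | add-random | re-drop-fixed
    term: str
    bic_before: float
    bic_after: float
    accepted: bool


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [vars(s) for s in self.steps]

    def accepted(self) -> list[SelectionStep]:
        return [s for s in self.steps if s.accepted]


def _droppable(terms: tuple[str, ...]) -> list[str]:
    protected = {p for t in terms for p in term_parents(t)}
    return [t for t in terms if t not in protected]


def _backward_pass(
    design: _Design,
    spec: ModelSpec,
    terms: tuple[str, ...],
    random_terms: tuple[str, ...],
    trace: SelectionTrace,
    phase: str,
) -> tuple[tuple[str, ...], FitResult]:
    current = _fit_design(design, spec, terms, random_terms, reml=False)
    while True:
        candidates = _droppable(current.spec.fixed_terms)
        if not candidates:
            break
        best: tuple[float, str, FitResult] | None = None
        for t in candidates:
            reduced = tuple(x for x in current.spec.fixed_terms if x != t)
            cand = _fit_design(
                design, spec, reduced, random_terms, reml=False, start_lam=current.raw.lam
            )
            bic = cand.bic if cand.converged else np.inf
            if best is None or bic < best[0]:
                best = (bic, t, cand)
        bic_after, term, cand_fit = best
        accepted = bic_after < current.bic + BIC_TIE_EPS
        trace.steps.append(
            SelectionStep(
                step=len(trace.steps),
                phase=phase,
                term=term,
                bic_before=float(current.bic),
                bic_after=float(bic_after),
                accepted=bool(accepted),
            )
        )
        if not accepted:
            break
        current = cand_fit
    return current.spec.fixed_terms, current


def simplify(table: pd.DataFrame, maximal: ModelSpec) -> tuple[ModelSpec, SelectionTrace]:
    """Three-phase BIC simplification of the maximal model; returns the
    final specification and the full selection trace (replaying the
    accepted steps of the trace reproduces the final spec)."""
    design = _Design(table, maximal)
    trace = SelectionTrace()

    base = tuple(maximal.base_random)
    terms, current = _backward_pass(
        design, maximal, maximal.fixed_terms, base, trace, "drop-fixed"
    )

    random_terms = base
    remaining = [f for f in maximal.random_terms if f not in base]
    current_reml = _fit_design(design, maximal, terms, random_terms, reml=True)
    while remaining:
        best = None
        for f in remaining:
            cand = _fit_design(
                design, maximal, terms, random_terms + (f,), reml=True
            )
            bic = cand.bic if cand.converged else np.inf
            if best is None or bic < best[0]:
                best = (bic, f, cand)
        bic_after, fac, cand_fit = best
        accepted = bic_after < current_reml.bic - BIC_TIE_EPS
        trace.steps.append(
            SelectionStep(
                step=len(trace.steps),
                phase="add-random",
                term=fac,
                bic_before=float(current_reml.bic),
                bic_after=float(bic_after),
                accepted=bool(accepted),
            )
        )
        if not accepted:
            break
        current_reml = cand_fit
        random_terms = random_terms + (fac,)
        remaining.remove(fac)

    terms, final_fit = _backward_pass(
        design, maximal, terms, random_terms, trace, "re-drop-fixed"
    )
    final_spec = replace(
        maximal, fixed_terms=terms, random_terms=random_terms, estimation="ML"
    )
    return final_spec, trace


_TERM_LABELS = {
    "log_edge_dist": "logEdgeDist",
    "first_slide": "firstSlide",
    "played_before": "playedBefore",
    "slide_number": "slideNumber",
    "I(slide_number ** 2)": "slideNumberSq",
    "viewing_condition": "viewingCondition",
    "age_class": "ageRange",
    "target_area": "targetArea",
    "target_lum_mean": "targetLuminanceMean",
    "target_contrast": "targetContrast",
}
_SCOPED_LABELS = {
    "log_pattern_diff": {"near": "logNearPatternDiff", "whole": "logWholePatternDiff"},
    "lum_dist_diff": {"near": "nearLuminanceDiff", "whole": "wholeLuminanceDiff"},
    "bg_lum_mean": {"near": "nearLuminanceMean", "whole": "wholeLuminanceMean"},
    "bg_contrast": {"near": "nearContrast", "whole": "wholeContrast"},
}


def term_label(term: str, scope: str = "near") -> str:
    parts = term.split(":")
    out = []
    for p in parts:
        if p in _SCOPED_LABELS:
            out.append(_SCOPED_LABELS[p][scope])
        else:
            out.append(_TERM_LABELS.get(p, p))
    return ":".join(out)


def report(result: FitResult, trace: SelectionTrace | None = None, scope: str = "near") -> dict:
    """Publication-style model report: term table (term, DF, F, P) with
    main effects above the interactions that contain them, a coefficient
    table, and the selection trace.  Deterministic for a given fit, so
    regenerating from a replayed trace is byte-identical."""
    terms = result.terms.copy()
    order = {t: i for i, t in enumerate(result.spec.fixed_terms)}
    terms["_deg"] = [t.count(":") for t in terms["term"]]
    terms["_ord"] = [order[t] for t in terms["term"]]
    terms = terms.sort_values(["_deg", "_ord"]).drop(columns=["_deg", "_ord"])
    terms.insert(0, "label", [term_label(t, scope) for t in terms["term"]])

    coef = pd.DataFrame(
        {
            "estimate": result.params,
            "se": result.bse,
            "t": result.tvalues,
        }
    )
    lines = [
        f"n = {result.n}, logLik = {result.llf:.4f}, BIC = {result.bic:.4f}",
        "random-effect SDs: "
        + ", ".join(f"{k} = {v:.4f}" for k, v in sorted(result.vc_sd.items()))
        + f", residual = {result.sigma_resid:.4f}",
        "",
        terms.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
    ]
    return {
        "terms": terms.reset_index(drop=True),
        "coefficients": coef,
        "trace": trace.to_records() if trace is not None else [],
        "summary": "\n".join(lines),
    }


# ---------------------------------------------------------------------------
# Maximal-model builders and the parameter-recovery harness


def default_maximal_spec(
    include_season: bool = False, quadratic_slide: bool = False
) -> ModelSpec:
    """The full maximal model: all nuisance terms, all camouflage
    covariates, and every camouflage x viewing and camouflage x slide
    2-way interaction plus viewing x slide."""
    mains = [
        "log_edge_dist",
        "first_slide",
        "played_before",
        "slide_number",
        "age_class",
        "viewing_condition",
        *CAMO_COVARIATES,
    ]
    if quadratic_slide:
        mains.append("I(slide_number ** 2)")
    inter = [f"viewing_condition:{c}" for c in CAMO_COVARIATES]
    inter += [f"slide_number:{c}" for c in CAMO_COVARIATES]
    inter.append("viewing_condition:slide_number")
    random = ("session_id", "photo_id") + (("season",) if include_season else ())
    return ModelSpec(fixed_terms=tuple(mains + inter), random_terms=random)


def recovery_maximal_spec(include_season: bool = False) -> ModelSpec:
    """A focused maximal model for the recovery harness: the nuisance
    terms, the five camouflage covariates the simulator acts on, and their
    viewing interactions plus viewing x slide."""
    camo = ("log_pattern_diff", "lum_dist_diff", "target_area", "bg_lum_mean", "bg_contrast")
    mains = (
        "log_edge_dist",
        "first_slide",
        "played_before",
        "slide_number",
        "age_class",
        "viewing_condition",
    ) + camo
    inter = tuple(f"viewing_condition:{c}" for c in camo) + (
        "viewing_condition:slide_number",
    )
    random = ("session_id", "photo_id") + (("season",) if include_season else ())
    return ModelSpec(fixed_terms=mains + inter, random_terms=random)


def recovery_behavior():
    """Generating coefficients for the focused recovery experiment: a
    strong viewing x pattern-difference interaction (0.4 on log time, about
    twice the magnitude the default study conditions emulate) against a null
    viewing x background-contrast interaction, with every other viewing
    interaction zeroed so the selection faces exactly one true and one null
    candidate among correlated photo-level covariates."""
    from .synthetic_data import BehaviorModel

    return BehaviorModel(
        i_view_pattern=0.4,
        i_view_lumdiff=0.0,
        i_view_area=0.0,
        i_view_bglum=0.0,
        i_view_contrast=0.0,
        i_view_slide=0.0,
    )


@dataclass
class RecoveryResult:
    """One simulated study pushed through the full pipeline and selection."""

    final_spec: ModelSpec
    final_fit: FitResult
    trace: SelectionTrace
    n_events: int
    n_retained: int


def recovery_study(
    n_sessions: int,
    library,
    behavior,
    seed: int,
    maximal: ModelSpec | None = None,
    scope: str = "near",
) -> RecoveryResult:
    """Simulate one study, clean it, and run the BIC selection.

    The generative model is the analysis model inverted, so the selection
    and the fitted coefficients can be compared against the known truth.
    """
    from .session_pipeline import derive_covariates, filter_events
    from .synthetic_data import simulate_study

    if maximal is None:
        maximal = recovery_maximal_spec()
    events = simulate_study(n_sessions, library, behavior, seed, scope=scope)
    retained, _rep = filter_events(events, timeout_s=behavior.timeout_s)
    table = derive_covariates(retained, library.metrics, scope=scope)
    final_spec, trace = simplify(table, maximal)
    final_fit = fit(table, final_spec)
    return RecoveryResult(
        final_spec=final_spec,
        final_fit=final_fit,
        trace=trace,
        n_events=len(events),
        n_retained=len(table),
    )
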