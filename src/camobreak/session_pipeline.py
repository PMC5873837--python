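"""Event-table cleaning, covariate derivation, and background-scope choice.

Filtering applies the study's two exclusion rules: slides on which the
participant made more than 2 incorrect clicks are dropped (the
"scatter-gun" guard), and timeout slides are dropped because no capture
time exists for them (timeouts are excluded, not censored).  Cleaned slides
are joined with the per-photograph camouflage metrics into the analysis
table; capture times, edge distances and pattern differences are
natural-log transformed.  When both the annulus ("near") and
whole-background covariate sets are available, the scope whose maximal
mixed model attains the lower BIC is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "filter_events",
    "derive_covariates",
    "choose_background_scope",
    "ScopeDecision",
    "ANALYSIS_COLUMNS",
]

#: maximum incorrect clicks per retained slide
MAX_INCORRECT_CLICKS = 2

ANALYSIS_COLUMNS = [
    "log_capture_time",
    "log_edge_dist",
    "slide_number",
    "first_slide",
    "played_before",
    "viewing_condition",
    "age_class",
    "log_pattern_diff",
    "lum_dist_diff",
    "target_area",
    "bg_lum_mean",
    "bg_contrast",
    "target_lum_mean",
    "target_contrast",
    "session_id",
    "photo_id",
]


def filter_events(
    events: pd.DataFrame, timeout_s: float = 30.0
) -> tuple[pd.DataFrame, dict]:
    """Apply the exclusion rules; return (retained slides, exclusion report).

    Malformed rows (unknown outcome, missing/nonpositive/over-timeout
    capture time on a capture, negative click counts) are counted in the
    report rather than silently dropped.  Reasons are assigned with
    precedence malformed > timeout > incorrect-clicks, so the report's
    counts plus the retained count always equal the input count.
    """
    df = events.copy()
    n_in = len(df)

    required = {"outcome", "capture_time_s", "n_incorrect_clicks"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns {sorted(missing)}")

    outcome = df["outcome"].astype(str)
    time = pd.to_numeric(df["capture_time_s"], errors="coerce")
    clicks = pd.to_numeric(df["n_incorrect_clicks"], errors="coerce")

    bad_outcome = ~outcome.isin(["capture", "timeout"])
    bad_clicks = clicks.isna() | (clicks < 0)
    bad_time = (outcome == "capture") & (
        time.isna() | (time <= 0) | (time > timeout_s)
    )
    malformed = bad_outcome | bad_clicks | bad_time

    is_timeout = (outcome == "timeout") & ~malformed
    scattergun = (outcome == "capture") & ~malformed & (clicks > MAX_INCORRECT_CLICKS)
    retained_mask = ~malformed & ~is_timeout & ~scattergun

    report = {
        "input_slides": int(n_in),
        "retained": int(retained_mask.sum()),
        "excluded_timeout": int(is_timeout.sum()),
        "excluded_incorrect_clicks": int(scattergun.sum()),
        "malformed": int(malformed.sum()),
    }
    return df.loc[retained_mask].reset_index(drop=True), report


def derive_covariates(
    retained: pd.DataFrame, metrics: pd.DataFrame, scope: str = "near"
) -> pd.DataFrame:
    """Join retained slides with photograph metrics into the analysis table.

    ``scope`` selects which background comparison supplies the camouflage
    covariates: "near" (the 15-500 px annulus) or "whole" (entire
    background minus target and spacer).  Natural logs are applied to
    capture time, edge distance and pattern difference.  Errors are loud: a
    retained slide without metrics, or a nonpositive pattern difference
    (log undefined), raises rather than guessing an offset.
    """
    if scope not in ("near", "whole"):
        raise ValueError("scope must be 'near' or 'whole'")
    if len(retained) == 0:
        return pd.DataFrame(columns=ANALYSIS_COLUMNS)
    if (retained["outcome"] != "capture").any():
        raise ValueError("derive_covariates expects filtered capture slides only")

    m = metrics.set_index("photo_id")
    unknown = set(retained["photo_id"].astype(str)) - set(m.index.astype(str))
    if unknown:
        raise ValueError(f"no metrics for photo ids: {sorted(unknown)[:5]}")

    joined = retained.merge(metrics, on="photo_id", how="left", validate="m:1")

    pat = joined[f"pattern_diff_{scope}"].to_numpy(dtype=float)
    if (pat <= 0).any():
        bad = joined.loc[pat <= 0, "photo_id"].unique()
        raise ValueError(
            f"nonpositive pattern difference (log undefined) for photos {list(bad)[:5]}"
        )
    edge = joined["edge_distance_px"].to_numpy(dtype=float)
    if (edge <= 0).any():
        raise ValueError("nonpositive edge distance (log undefined)")

    out = pd.DataFrame(
        {
            "log_capture_time": np.log(joined["capture_time_s"].to_numpy(dtype=float)),
            "log_edge_dist": np.log(edge),
            "slide_number": joined["slide_number"].astype(int),
            "first_slide": (joined["slide_number"].astype(int) == 1).astype(int),
            "played_before": joined["played_before"]
            .astype(str)
            .isin(["True", "true", "1"])
            .astype(int),
            "viewing_condition": joined["viewing_condition"].astype(str),
            "age_class": joined["age_class"].astype(str),
            "log_pattern_diff": np.log(pat),
            "lum_dist_diff": joined[f"lum_dist_diff_{scope}"].astype(float),
            "target_area": joined["target_area"].astype(float),
            "bg_lum_mean": joined[f"mean_lum_{scope}"].astype(float),
            "bg_contrast": joined[f"contrast_{scope}"].astype(float),
            "target_lum_mean": joined["mean_lum_target"].astype(float),
            "target_contrast": joined["contrast_target"].astype(float),
            "session_id": joined["session_id"].astype(str),
            "photo_id": joined["photo_id"].astype(str),
        }
    )
    if "season" in joined.columns:
        out["season"] = joined["season"].astype(str)
    if not np.all(np.isfinite(out.select_dtypes(include=[np.number]).to_numpy())):
        raise ValueError("non-finite covariate values in analysis table")
    return out


@dataclass(frozen=True)
class ScopeDecision:
    """Outcome of the near-vs-whole background comparison."""

    scope: str
    bic_near: float
    bic_whole: float


def choose_background_scope(
    table_near: pd.DataFrame,
    table_whole: pd.DataFrame,
    maximal,
) -> ScopeDecision:
    """Fit the maximal model on both covariate scopes; lower BIC wins.

    ``maximal`` is the lmm_selection.ModelSpec for the maximal model.  Ties
    (|dBIC| <= 1e-6) resolve to "near", the surround the search task itself
    presents.  A fit failure propagates with the scope label attached.
    """
    from .lmm_selection import fit  # deferred to avoid a module cycle

    bics = {}
    for scope, table in (("near", table_near), ("whole", table_whole)):
        try:
            bics[scope] = fit(table, maximal).bic
        except Exception as exc:
            raise RuntimeError(f"maximal model failed for scope {scope!r}: {exc}") from exc
    scope = "near" if bics["near"] <= bics["whole"] + 1e-6 else "whole"
    return ScopeDecision(scope=scope, bic_near=bics["near"], bic_whole=bics["whole"])
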