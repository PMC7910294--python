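"""Tiered hit-advancement logic: duplicate primary screen, triplicate
confirmation, three-point dose ranging, stimulus-independence check, and
efficacy/diversity shortlisting.

Advancement thresholds follow the screen's published criteria: an effect of
at least +/-20% versus the stimulated vehicle on either channel
(inclusive), replicate variability (percent CV) strictly below 15% on the
qualifying channel, and strictly less than 50% cell loss
(cell_ratio > 0.5).  Cytotoxicity is evaluated *before* the effect call so
that cell-loss artifacts can never be reported as inhibition.

All threshold comparisons use a 1e-9 absolute guard so that a mean
activity stored as the nearest float to 0.80 (whose percent change prints
as -20 but sits one ulp short) is classified inclusively; 0.801 / 1.199
remain non-hits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientReplicatesError, ScreenError
from .qc import CHANNELS, normalize_screen

_EPS = 1e-9

HIT_VERDICTS = ("hit_up", "hit_down")


@dataclass(frozen=True)
class Thresholds:
    """Advancement criteria, in percent.

    effect_pct : minimum |percent change| vs stimulated vehicle (inclusive)
    cv_pct : replicate percent CV above which a qualifying channel is
        rejected as too variable (exclusive: CV must be < this)
    max_cell_loss_pct : maximum tolerated cell loss (exclusive: loss must
        be < this, i.e. cell_ratio > 1 - this/100)
    """

    effect_pct: float = 20.0
    cv_pct: float = 15.0
    max_cell_loss_pct: float = 50.0

    @property
    def min_cell_ratio(self) -> float:
        return 1.0 - self.max_cell_loss_pct / 100.0


def summarize_tier(normalized: pd.DataFrame, by_dose: bool = False) -> pd.DataFrame:
    """Per-compound replicate statistics from normalized wells.

    Returns one row per compound (per dose when ``by_dose``) with mean
    activity, percent change, percent CV (sample SD over mean) per channel,
    mean cell ratio and replicate count.  Wells with zero cells contribute
    cell_ratio 0 but no activity values.
    """
    cmp = normalized[normalized["role"] == "compound"]
    keys = ["compound_id", "concentration_um"] if by_dose else ["compound_id"]
    rows = []
    for key, grp in cmp.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(keys, key))
        row["n_rep"] = len(grp)
        row["cell_ratio"] = float(grp["cell_ratio"].mean())
        for ch in CHANNELS:
            act = grp[f"activity_{ch}"].dropna()
            mean = float(act.mean()) if len(act) else np.nan
            sd = float(act.std(ddof=1)) if len(act) >= 2 else np.nan
            row[f"mean_{ch}"] = mean
            row[f"percent_change_{ch}"] = (mean - 1.0) * 100.0
            row[f"cv_{ch}"] = (
                sd / mean * 100.0 if (len(act) >= 2 and mean != 0) else np.nan)
            # largest single-replicate change: a channel can "qualify but be
            # too variable" when individual wells reach the effect threshold
            # even though the (noisy) mean does not
            row[f"max_change_{ch}"] = (
                float((act - 1.0).abs().max() * 100.0) if len(act) else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _classify(row: pd.Series, thr: Thresholds) -> tuple[str, str]:
    """Verdict and reason for one compound summary, in rule order:
    cytotoxicity, then variability, then effect."""
    if row["cell_ratio"] <= thr.min_cell_ratio + _EPS:
        return ("excluded_cytotoxic",
                f"cell_ratio {row['cell_ratio']:.3f} <= {thr.min_cell_ratio:g}")
    qualifying = {}
    variable = {}
    for ch in CHANNELS:
        pc = row[f"percent_change_{ch}"]
        if not np.isfinite(pc):
            continue
        cv = row[f"cv_{ch}"]
        too_variable = np.isfinite(cv) and cv >= thr.cv_pct - _EPS
        if abs(pc) >= thr.effect_pct - _EPS and not too_variable:
            qualifying[ch] = pc
            continue
        # a channel "would otherwise qualify" when its mean, or any single
        # replicate, reaches the effect threshold
        max_change = row.get(f"max_change_{ch}", np.nan)
        reaches = abs(pc) >= thr.effect_pct - _EPS or (
            np.isfinite(max_change) and max_change >= thr.effect_pct - _EPS)
        if too_variable and reaches:
            variable[ch] = cv
    if qualifying:
        best = max(qualifying, key=lambda ch: (abs(qualifying[ch]), ch))
        direction = "hit_up" if qualifying[best] > 0 else "hit_down"
        return (direction,
                f"{best} {qualifying[best]:+.1f}% "
                f"(cv {row[f'cv_{best}']:.1f}%, cell_ratio {row['cell_ratio']:.2f})")
    if variable:
        detail = ", ".join(f"{ch} cv {cv:.1f}%" for ch, cv in sorted(variable.items()))
        return ("excluded_variable", f"effect qualifies but too variable: {detail}")
    pcs = ", ".join(f"{ch} {row[f'percent_change_{ch}']:+.1f}%" for ch in CHANNELS)
    return ("not_hit", pcs)


def _filter_tier(summaries: pd.DataFrame, thresholds: Thresholds,
                 min_replicates: int) -> pd.DataFrame:
    if summaries.empty:
        return summaries.assign(verdict=pd.Series(dtype=object),
                                reason=pd.Series(dtype=object))
    short = summaries[summaries["n_rep"] < min_replicates]
    if not short.empty:
        raise InsufficientReplicatesError(
            f"compounds with < {min_replicates} replicate wells: "
            f"{sorted(short['compound_id'])}")
    out = summaries.copy().reset_index(drop=True)
    verdicts = out.apply(_classify, axis=1, thr=thresholds, result_type="expand")
    out["verdict"] = verdicts[0]
    out["reason"] = verdicts[1]
    return out.sort_values("compound_id", kind="stable").reset_index(drop=True)


def primary_filter(summaries: pd.DataFrame,
                   thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Apply the duplicate-well primary-screen criteria.

    Rule order per compound: (1) cytotoxicity exclusion, (2) variability
    exclusion on channels whose effect would otherwise qualify, (3) effect
    call on either channel, direction taken from the larger-magnitude
    qualifying channel.  Requires >= 2 replicate wells per compound.
    """
    return _filter_tier(summaries, thresholds or Thresholds(), min_replicates=2)


def secondary_filter(summaries: pd.DataFrame, primary_hits,
                     thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Triplicate confirmation of primary hits.

    Only compounds that were primary hits are evaluated (the funnel never
    resurrects a compound); the same rule structure applies on triplicate
    statistics.  ``primary_hits`` is a list of compound ids or the primary
    result table.
    """
    if isinstance(primary_hits, pd.DataFrame):
        primary_hits = hit_ids(primary_hits)
    primary_hits = set(primary_hits)
    evaluated = summaries[summaries["compound_id"].isin(primary_hits)]
    return _filter_tier(evaluated, thresholds or Thresholds(), min_replicates=3)


def hit_ids(results: pd.DataFrame) -> list[str]:
    """Compound ids with a hit verdict, sorted."""
    if results.empty:
        return []
    return sorted(results.loc[results["verdict"].isin(HIT_VERDICTS), "compound_id"])


def dose_select(tertiary: pd.DataFrame,
                thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Choose a follow-up concentration per compound from the dose-ranging
    tier: the dose giving the maximal |percent change| on either channel
    among doses without disqualifying cell loss, ties broken by higher cell
    ratio then lower dose.

    ``tertiary`` is a per-compound, per-dose summary (``summarize_tier``
    with ``by_dose=True``).  Compounds with no viable dose are returned
    with verdict ``excluded_cytotoxic``; compounds whose best effect is
    sub-threshold get ``not_hit`` at their max-effect dose.
    """
    thr = thresholds or Thresholds()
    if tertiary.empty:
        raise ScreenError("empty dose set")
    rows = []
    for cid, grp in tertiary.groupby("compound_id", sort=True):
        if grp["concentration_um"].nunique() < 2:
            raise ScreenError(f"compound {cid}: need summaries at >= 2 doses")
        grp = grp.copy()
        grp["score"] = grp[[f"percent_change_{ch}" for ch in CHANNELS]].abs().max(axis=1)
        viable = grp[grp["cell_ratio"] > thr.min_cell_ratio + _EPS]
        if viable.empty:
            rows.append({"compound_id": cid, "chosen_dose": np.nan,
                         "percent_change_ccl2": np.nan, "percent_change_icam1": np.nan,
                         "cell_ratio": np.nan, "verdict": "excluded_cytotoxic",
                         "rationale": "no dose with < 50% cell loss"})
            continue
        best = viable.sort_values(
            by=["score", "cell_ratio", "concentration_um"],
            ascending=[False, False, True], kind="stable").iloc[0]
        # an exact-tie competitor at lower dose with equal cell ratio wins;
        # the stable sort above already encodes score desc, ratio desc, dose asc
        verdict = "not_hit"
        if best["score"] >= thr.effect_pct - _EPS:
            larger = max(CHANNELS, key=lambda ch: (abs(best[f"percent_change_{ch}"]), ch))
            verdict = "hit_up" if best[f"percent_change_{larger}"] > 0 else "hit_down"
        rows.append({
            "compound_id": cid, "chosen_dose": float(best["concentration_um"]),
            "percent_change_ccl2": float(best["percent_change_ccl2"]),
            "percent_change_icam1": float(best["percent_change_icam1"]),
            "cell_ratio": float(best["cell_ratio"]), "verdict": verdict,
            "rationale": (f"max |effect| {best['score']:.1f}% at "
                          f"{best['concentration_um']:g} uM with cell_ratio "
                          f"{best['cell_ratio']:.2f}")})
    return pd.DataFrame(rows)


def independence_check(summaries: pd.DataFrame,
                       threshold_pct: float = 20.0) -> pd.DataFrame:
    """Flag compounds with stimulus-independent (basal) activity.

    ``summaries`` come from an unstimulated run normalized to vehicle_only
    wells.  A compound whose basal |percent change| reaches the threshold
    on either channel is flagged ``basal_up`` / ``basal_down``
    (confounded); an entirely clean screen has zero flags.
    """
    if summaries.empty:
        raise ScreenError("no unstimulated summaries supplied")
    rows = []
    for _, row in summaries.iterrows():
        flag = "none"
        worst = 0.0
        for ch in CHANNELS:
            pc = row[f"percent_change_{ch}"]
            if np.isfinite(pc) and abs(pc) >= threshold_pct - _EPS and abs(pc) > abs(worst):
                worst = pc
                flag = "basal_up" if pc > 0 else "basal_down"
        rows.append({"compound_id": row["compound_id"], "flag": flag,
                     "basal_change_ccl2": row["percent_change_ccl2"],
                     "basal_change_icam1": row["percent_change_icam1"]})
    return pd.DataFrame(rows).sort_values("compound_id").reset_index(drop=True)


def rank_and_diversify(confirmed: pd.DataFrame,
                       annotations: pd.DataFrame | None,
                       k: int, max_per_class: int = 2) -> pd.DataFrame:
    """Shortlist hits by efficacy under a therapeutic-class diversity cap.

    Sort confirmed hits by their best-channel |percent change| descending
    (ties by lexicographic compound id) and greedily take compounds,
    allowing at most ``max_per_class`` from any one therapeutic class,
    until ``k`` are selected.  Unannotated compounds fall in class
    ``"unknown"``.  Returns the shortlist with a ``shortfall`` attribute in
    ``DataFrame.attrs`` when fewer than ``k`` are available.
    """
    if k <= 0:
        raise ConfigError(f"shortlist size must be positive, got {k}")
    if max_per_class <= 0:
        raise ConfigError("max_per_class must be positive")
    hits = confirmed[confirmed["verdict"].isin(HIT_VERDICTS)].copy()
    classes = {}
    if annotations is not None and len(annotations):
        classes = dict(zip(annotations["compound_id"],
                           annotations["therapeutic_class"]))
    hits["therapeutic_class"] = [classes.get(c, "unknown")
                                 for c in hits["compound_id"]]
    hits["score"] = hits[[f"percent_change_{ch}" for ch in CHANNELS]].abs().max(axis=1)
    hits = hits.sort_values(by=["score", "compound_id"],
                            ascending=[False, True], kind="stable")
    taken = []
    per_class: dict[str, int] = {}
    for _, row in hits.iterrows():
        if len(taken) >= k:
            break
        cls = row["therapeutic_class"]
        if per_class.get(cls, 0) >= max_per_class:
            continue
        per_class[cls] = per_class.get(cls, 0) + 1
        taken.append(row)
    cols = ["compound_id", "therapeutic_class", "score", "verdict",
            "percent_change_ccl2", "percent_change_icam1"]
    out = pd.DataFrame(taken).reset_index(drop=True)
    out = out[[c for c in cols if c in out.columns]] if len(out) else pd.DataFrame(
        columns=cols)
    out.attrs["shortfall"] = max(0, k - len(out))
    return out


# ---------------------------------------------------------------------------
# end-to-end funnel on simulated screens
# ---------------------------------------------------------------------------

@dataclass
class FunnelResult:
    truth: object
    primary: pd.DataFrame
    secondary: pd.DataFrame
    doses: pd.DataFrame | None
    independence: pd.DataFrame | None
    shortlist: pd.DataFrame | None

    @property
    def primary_hits(self) -> list[str]:
        return hit_ids(self.primary)

    @property
    def confirmed_hits(self) -> list[str]:
        return hit_ids(self.secondary)

    def tier_tables(self) -> dict[str, pd.DataFrame]:
        out = {"primary": self.primary, "secondary": self.secondary}
        if self.doses is not None:
            out["tertiary"] = self.doses
        if self.independence is not None:
            out["independence"] = self.independence
        return out


def run_funnel(config, noise=None, thresholds: Thresholds | None = None,
               annotations: pd.DataFrame | None = None,
               run_tertiary: bool = True, run_independence: bool = True,
               shortlist_k: int | None = None,
               max_per_class: int = 2) -> FunnelResult:
    """Simulate and triage a full screen against one ground truth.

    Primary (duplicate) -> secondary (triplicate, primary hits only) ->
    tertiary dose ranging and independence check on confirmed hits ->
    optional efficacy/diversity shortlist.  Tier datasets use offset seeds
    derived from ``config.seed`` so noise draws are independent between
    tiers while the whole funnel stays reproducible.
    """
    from .simulate import simulate_screen  # deferred: simulate imports io

    thr = thresholds or Thresholds()
    primary_ds, truth = simulate_screen(config, noise, tier="primary")
    primary_sum = summarize_tier(normalize_screen(primary_ds))
    primary = primary_filter(primary_sum, thr)
    p_hits = hit_ids(primary)

    secondary = primary.iloc[0:0].copy()
    confirmed: list[str] = []
    if p_hits:
        cfg2 = replace(config, seed=(config.seed + 100003) % (2 ** 31))
        sec_ds, _ = simulate_screen(cfg2, noise, tier="secondary", truth=truth,
                                    compound_ids=p_hits)
        secondary = secondary_filter(summarize_tier(normalize_screen(sec_ds)),
                                     p_hits, thr)
        confirmed = hit_ids(secondary)

    doses = None
    if run_tertiary and confirmed:
        cfg3 = replace(config, seed=(config.seed + 200003) % (2 ** 31))
        ter_ds, _ = simulate_screen(cfg3, noise, tier="tertiary", truth=truth,
                                    compound_ids=confirmed)
        doses = dose_select(
            summarize_tier(normalize_screen(ter_ds), by_dose=True), thr)

    independence = None
    if run_independence and confirmed:
        cfg4 = replace(config, seed=(config.seed + 300007) % (2 ** 31))
        ind_ds, _ = simulate_screen(cfg4, noise, tier="independence", truth=truth,
                                    compound_ids=confirmed)
        independence = independence_check(
            summarize_tier(normalize_screen(ind_ds)), thr.effect_pct)

    shortlist = None
    if shortlist_k is not None and confirmed:
        shortlist = rank_and_diversify(secondary, annotations, k=shortlist_k,
                                       max_per_class=max_per_class)
    return FunnelResult(truth=truth, primary=primary, secondary=secondary,
                        doses=doses, independence=independence,
                        shortlist=shortlist)
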