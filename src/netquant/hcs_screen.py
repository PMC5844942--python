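"""High-content screening layer: per-compound modulation calls and filters.

Each compound well's %NETotic value is scored as a robust z against the
matching untreated control population — unstimulated compound wells against
unstimulated-untreated controls (induction side), PMA-stimulated compound
wells against PMA-untreated controls (inhibition/enhancement side):

    z = (pct - median(controls)) / (1.4826 x MAD(controls))

median/MAD rather than mean/SD because a screen's strong hits would inflate
a naive SD. When the scaled MAD collapses (unstimulated controls are almost
all exactly 0% NETotic) a floor of ``sigma_floor`` percentage points keeps z
finite and conservative.

A compound is an induction hit when z >= z_cut at >= min_hit_doses doses in
the unstimulated condition; inhibition/enhancement hits are z <= -z_cut /
z >= z_cut in the PMA condition. Opposite significant calls in the lower vs
upper half of the dose range make a biphasic modulator (e.g. inhibition at
low dosage and induction at high dosage). Compounds with an apoptotic-body
phenotype at a hit dose, and compounds on the configured exclusion list
(neutropenia or other neutrophil-death associations from the literature),
are excluded from the selected set.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = [
    "ScreenConfig",
    "CompoundResult",
    "robust_z",
    "compound_responses",
    "call_modulator",
    "apply_filters",
    "normalize_doseresponse",
    "funnel_counts",
]


@dataclass
class ScreenConfig:
    """Hit-calling configuration.

    ``min_hit_doses`` defaults to 2: with ~560 compound wells per screen, a
    3-sigma single-well cut alone admits of order one spurious call per run;
    requiring the effect to replicate at two of five doses suppresses that
    while leaving real dose-responsive modulators (significant at 3+ doses)
    untouched.
    """

    z_cut: float = 3.0
    min_hit_doses: int = 2
    apoptosis_well_fraction_cut: float = 0.25
    sigma_floor: float = 1.0
    exclusion_list: dict[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.z_cut <= 0:
            raise ValueError("z_cut must be > 0")
        if self.min_hit_doses < 1:
            raise ValueError("min_hit_doses must be >= 1")


@dataclass
class CompoundResult:
    """Dose-response vector, modulation calls and exclusion state for one compound."""

    compound_name: str
    doses: list[float]
    pct_netotic_unstim: list[float]
    pct_netotic_pma: list[float]
    z_unstim: list[float]
    z_pma: list[float]
    induction_hit: bool = False
    inhibition_hit: bool = False
    enhancement_hit: bool = False
    modulator_class: str = "none"  # {inducer, inhibitor, enhancer, biphasic, none}
    excluded: bool = False
    exclusion_reason: str = "none"  # {apoptotic_phenotype, exclusion_list, none}

    @property
    def is_hit(self) -> bool:
        return self.induction_hit or self.inhibition_hit or self.enhancement_hit


def robust_z(values: np.ndarray, controls: np.ndarray, sigma_floor: float = 1.0) -> np.ndarray:
    """Robust z-scores of ``values`` against a control population."""
    controls = np.asarray(controls, dtype=float)
    med = float(np.median(controls))
    sigma = 1.4826 * float(np.median(np.abs(controls - med)))
    sigma = max(sigma, sigma_floor)
    return (np.asarray(values, dtype=float) - med) / sigma


def _control_pcts(summaries: pd.DataFrame, condition: str) -> np.ndarray:
    ctrl = summaries[
        (summaries["condition"] == condition) & (summaries["compound"] == "")
    ]["pct_netotic"].dropna()
    if ctrl.empty:
        raise ValueError(f"no untreated control wells for condition {condition!r}: cannot score")
    return ctrl.to_numpy(dtype=float)


def compound_responses(
    summaries: pd.DataFrame, config: ScreenConfig | None = None
) -> pd.DataFrame:
    """Per-(compound, dose) response table with robust z per condition.

    ``summaries`` needs one row per well with columns condition, compound,
    dose_molar, pct_netotic, apoptotic_fraction. Replicate wells of a
    (compound, dose, condition) cell are averaged before scoring. The result
    is independent of input row order.
    """
    config = config or ScreenConfig()
    required = {"condition", "compound", "dose_molar", "pct_netotic", "apoptotic_fraction"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")
    # control wells round-trip through CSV with an empty compound cell
    summaries = summaries.assign(compound=summaries["compound"].fillna(""))

    ctrl_unstim = _control_pcts(summaries, "unstimulated")
    ctrl_pma = _control_pcts(summaries, "PMA")

    comp = summaries[(summaries["compound"] != "")
                     & summaries["condition"].isin(["unstimulated", "PMA"])]
    agg = (
        comp.groupby(["compound", "dose_molar", "condition"], sort=True)
        .agg(pct_netotic=("pct_netotic", "mean"),
             apoptotic_fraction=("apoptotic_fraction", "mean"))
        .reset_index()
    )
    wide = agg.pivot(index=["compound", "dose_molar"], columns="condition",
                     values=["pct_netotic", "apoptotic_fraction"])
    wide.columns = [f"{a}_{'unstim' if b == 'unstimulated' else 'pma'}" for a, b in wide.columns]
    wide = wide.reset_index().sort_values(["compound", "dose_molar"]).reset_index(drop=True)
    for col in ("pct_netotic_unstim", "pct_netotic_pma",
                "apoptotic_fraction_unstim", "apoptotic_fraction_pma"):
        if col not in wide.columns:
            wide[col] = np.nan
    wide["z_unstim"] = robust_z(wide["pct_netotic_unstim"].to_numpy(), ctrl_unstim,
                                config.sigma_floor)
    wide["z_pma"] = robust_z(wide["pct_netotic_pma"].to_numpy(), ctrl_pma,
                             config.sigma_floor)
    return wide


def _half_split(n: int) -> tuple[slice, slice]:
    """Lower/upper half of an ordered dose range; odd middle dose unassigned."""
    half = n // 2
    return slice(0, half), slice(n - half, n)


def call_modulator(table: pd.DataFrame, config: ScreenConfig | None = None) -> CompoundResult:
    """Classify one compound from its per-dose response table.

    ``table`` is the :func:`compound_responses` slice for a single compound
    (>= 2 doses, ascending). Calls: induction (unstimulated z >= z_cut),
    inhibition (PMA z <= -z_cut), enhancement (PMA z >= z_cut), each needing
    ``min_hit_doses`` significant doses. Modulator class is biphasic when a
    condition shows significant calls of opposite direction in the lower vs
    upper half of the dose range; otherwise the single significant direction.
    """
    config = config or ScreenConfig()
    table = table.sort_values("dose_molar").reset_index(drop=True)
    if len(table) < 2:
        raise ValueError("modulator calling needs >= 2 doses")
    names = set(table["compound"])
    if len(names) != 1:
        raise ValueError(f"table must describe exactly one compound, got {sorted(names)}")

    z_un = table["z_unstim"].to_numpy(dtype=float)
    z_pma = table["z_pma"].to_numpy(dtype=float)
    cut, need = config.z_cut, config.min_hit_doses

    induction = int(np.nansum(z_un >= cut)) >= need
    inhibition = int(np.nansum(z_pma <= -cut)) >= need
    enhancement = int(np.nansum(z_pma >= cut)) >= need

    def biphasic(z: np.ndarray) -> bool:
        lo, hi = _half_split(len(z))
        neg_lo = bool(np.nansum(z[lo] <= -cut))
        pos_lo = bool(np.nansum(z[lo] >= cut))
        neg_hi = bool(np.nansum(z[hi] <= -cut))
        pos_hi = bool(np.nansum(z[hi] >= cut))
        return (neg_lo and pos_hi) or (pos_lo and neg_hi)

    if (inhibition and enhancement and biphasic(z_pma)) or (
        induction and biphasic(z_un)
    ):
        cls = "biphasic"
    elif induction and not (inhibition or enhancement):
        cls = "inducer"
    elif inhibition and not enhancement:
        cls = "inhibitor"
    elif enhancement and not inhibition:
        cls = "enhancer"
    elif inhibition and enhancement:
        # both directions but not cleanly split by dose: dominant direction
        cls = "inhibitor" if np.nanmax(np.abs(z_pma[z_pma <= -cut])) >= np.nanmax(z_pma) else "enhancer"
    elif induction:
        cls = "inducer"
    else:
        cls = "none"

    return CompoundResult(
        compound_name=str(table["compound"].iloc[0]),
        doses=[float(d) for d in table["dose_molar"]],
        pct_netotic_unstim=[float(x) for x in table["pct_netotic_unstim"]],
        pct_netotic_pma=[float(x) for x in table["pct_netotic_pma"]],
        z_unstim=[float(x) for x in z_un],
        z_pma=[float(x) for x in z_pma],
        induction_hit=induction,
        inhibition_hit=inhibition,
        enhancement_hit=enhancement,
        modulator_class=cls,
    )


def apply_filters(
    results: list[CompoundResult],
    responses: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> list[CompoundResult]:
    """Exclude apoptosis-confounded and literature-excluded compounds.

    A hit compound is excluded with reason ``apoptotic_phenotype`` when its
    mean apoptotic well fraction exceeds the cut at any dose carrying a
    significant call, and with reason ``exclusion_list`` when its name is on
    the configured list. Non-hit compounds pass through unfiltered (there is
    nothing to select them for). Returns updated results; selection is
    ``r.is_hit and not r.excluded``.
    """
    config = config or ScreenConfig()
    out: list[CompoundResult] = []
    for res in results:
        excluded, reason = False, "none"
        if res.is_hit:
            sub = responses[responses["compound"] == res.compound_name].sort_values("dose_molar")
            z_un = sub["z_unstim"].to_numpy(dtype=float)
            z_pma = sub["z_pma"].to_numpy(dtype=float)
            apo_un = sub["apoptotic_fraction_unstim"].to_numpy(dtype=float)
            apo_pma = sub["apoptotic_fraction_pma"].to_numpy(dtype=float)
            hit_apo = np.concatenate([
                apo_un[np.abs(z_un) >= config.z_cut],
                apo_pma[np.abs(z_pma) >= config.z_cut],
            ])
            hit_apo = hit_apo[~np.isnan(hit_apo)]
            if hit_apo.size and hit_apo.max() > config.apoptosis_well_fraction_cut:
                excluded, reason = True, "apoptotic_phenotype"
            elif res.compound_name in config.exclusion_list:
                excluded, reason = True, "exclusion_list"
        out.append(
            CompoundResult(
                **{**res.__dict__, "excluded": excluded, "exclusion_reason": reason}
            )
        )
    return out


def funnel_counts(results: list[CompoundResult]) -> dict:
    """Screen funnel: screened / per-direction hits / surviving selected set."""
    selected = sorted(r.compound_name for r in results if r.is_hit and not r.excluded)
    return {
        "screened": len(results),
        "induction_hits": sum(r.induction_hit for r in results),
        "inhibition_hits": sum(r.inhibition_hit for r in results),
        "enhancement_hits": sum(r.enhancement_hit for r in results),
        "selected": len(selected),
        "selected_names": selected,
    }


def normalize_doseresponse(
    readouts: pd.DataFrame,
    media_treatment: str = "media",
    value_col: str = "value",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize a scalar readout table to each plate's media-only control.

    ``readouts`` needs columns plate (one plate per donor), treatment and the
    value column. Every plate must contain a media-control row with a
    positive value; normalized = raw / media (so donor-to-donor baseline
    differences divide out). Returns (per-row normalized table, per-treatment
    mean +/- SEM summary across plates).
    """
    required = {"plate", "treatment", value_col}
    missing = required - set(readouts.columns)
    if missing:
        raise ValueError(f"readouts missing columns: {sorted(missing)}")
    media = readouts[readouts["treatment"] == media_treatment]
    media_by_plate = media.groupby("plate")[value_col].mean()
    norm = readouts.copy()
    for plate in norm["plate"].unique():
        if plate not in media_by_plate.index:
            raise ValueError(f"plate {plate!r} has no media-control value")
        m = float(media_by_plate[plate])
        if m <= 0:
            raise ValueError(f"plate {plate!r} media-control value must be > 0, got {m}")
    norm["normalized"] = [
        float(row[value_col]) / float(media_by_plate[row["plate"]])
        for _, row in norm.iterrows()
    ]
    summary_rows = []
    for treatment, grp in norm.groupby("treatment", sort=True):
        vals = grp["normalized"].to_numpy(dtype=float)
        summary_rows.append({
            "treatment": treatment,
            "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"),
            "n": len(vals),
        })
    return norm, pd.DataFrame(summary_rows)
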