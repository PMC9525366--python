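"""Model parameters for the maternal-fetal iodine biokinetic model.

The model describes the whole-body kinetics of iodide in a pregnant woman
and her fetus as a network of 23 well-mixed compartments.  Most exchanges
are first-order; transport steps mediated by the sodium/iodide symporter
(NIS) — into the thyroid, salivary glands, gastric mucosa, placenta and the
fetal thyroid — are saturable and described by Michaelis–Menten kinetics.

All parameter tables are shipped as package data (CSV) together with a JSON
manifest mapping the published row labels to compartment pairs.  Rate
constants are in d⁻¹, amounts in µmol, volumes in litres, masses in grams.

The Michaelis–Menten parameters are derived from the linear-regime
first-order rate constants: with the NIS Michaelis constant
``Km = 9 µmol·l⁻¹`` and the distribution volume ``Vd`` of the source
compartment,

    Tmax   = Km · k · Vd     (µmol·d⁻¹, maximum carrier capacity)
    Km#    = Km · Vd         (µmol, Michaelis constant as an amount)

so that for amounts far below Km# the carrier flux reduces to ``k · m``
and the saturable model coincides with the first-order one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional

import pandas as pd

#: Pregnancy ages (post-conceptional weeks) for which parameters are tabulated.
SUPPORTED_WEEKS: tuple[int, ...] = (0, 3, 8, 12, 16, 24, 32, 36, 38)

#: The fetal thyroid starts concentrating iodide at this pregnancy age.
FIRST_FETAL_WEEK = 12

#: All compartments of the mother-fetus model.
COMPARTMENTS: tuple[str, ...] = (
    "stomach",
    "small_intestine",
    "upper_large_intestine",
    "lower_large_intestine",
    "feces",
    "blood",
    "thyroid_iodide",
    "thyroid_organic",
    "iodide_other",
    "organic_other",
    "salivary_glands",
    "gastric_secretory",
    "kidneys",
    "urinary_bladder",
    "urine",
    "ovaries",
    "uteroplacental_iodide",
    "uteroplacental_organic",
    "amniotic_iodide",
    "amniotic_organic",
    "fetal_iodide",
    "fetal_thyroid",
    "fetal_organic",
)

#: NIS Michaelis constant for iodide, µmol·l⁻¹ (human symporter).
KM_CONC_UMOL_PER_L = 9.0

#: Physical half-life of I-131 in days, and the resulting decay constant d⁻¹.
I131_HALF_LIFE_D = 8.02
DECAY_CONSTANT_PER_D = math.log(2.0) / I131_HALF_LIFE_D

#: Specific activity of I-131 (Bq per gram).
I131_SPECIFIC_ACTIVITY_BQ_PER_G = 4.6e15

#: Molar masses, g·mol⁻¹.
MOLAR_MASS_I131 = 131.0
MOLAR_MASS_STABLE = 126.904

#: Iodine uptake (µmol) that saturates the adult gland and switches on the
#: Wolff–Chaikoff block: +350 µg above the ~8,000 µg basal gland content.
WC_THRESHOLD_MATERNAL_UMOL = 2.7581
#: The same saturation expressed as a fraction of gland iodine content
#: (350/8000), applied to the fetal gland for lack of measured values.
WC_SATURATION_FRACTION = 350.0 / 8000.0
#: Basal iodine concentration of the mature gland, µg per g of tissue
#: (8,000 µg in a 16 g gland); used to scale the fetal saturation threshold.
ADULT_GLAND_IODINE_UG_PER_G = 8000.0 / 16.0
#: Escape from the Wolff–Chaikoff block, hours after switch-on.
WC_DURATION_H = 36.0


@dataclass(frozen=True)
class Physiology:
    """Per-week anatomical quantities used for kinetics and dosimetry."""

    week: int
    vd_maternal_blood_l: float
    thyroid_weight_maternal_g: float
    lobe_radius_maternal_cm: float
    fetal_weight_g: Optional[float]
    vd_fetal_l: Optional[float]
    thyroid_weight_fetal_g: Optional[float]
    lobe_radius_fetal_cm: Optional[float]

    @property
    def has_fetal_thyroid(self) -> bool:
        return self.thyroid_weight_fetal_g is not None


@dataclass(frozen=True)
class FlowSpec:
    """One directed transfer between compartments.

    ``law`` is ``"first_order"`` (flux = k·m) or ``"michaelis_menten"``
    (flux = Tmax·m/(Km# + m_total), both iodine species competing in the
    denominator).  ``wc_gated`` marks carrier flows into a thyroid gland
    that are shut while that gland's Wolff–Chaikoff block is active.
    """

    name: str
    source: str
    target: str
    law: str
    k: float
    km_abs: Optional[float] = None
    tmax: Optional[float] = None
    wc_gated: bool = False
    gland: Optional[str] = None  # "maternal" | "fetal" for gated flows

    @property
    def active(self) -> bool:
        return self.k > 0.0


@dataclass(frozen=True)
class ModelParameters:
    """Complete, internally consistent parameter set for one pregnancy week.

    ``decay_scope`` selects where radioactive decay acts: ``"thyroid"``
    removes radioiodine only inside the two glands (the formulation behind
    the published dose tables, where the decay sink is attached to the
    thyroid compartments), while ``"all"`` decays every compartment (the
    physically complete variant; gland decays still feed the dose sinks).
    """

    week: int
    physiology: Physiology
    flows: tuple[FlowSpec, ...]
    decay_constant: float = DECAY_CONSTANT_PER_D
    decay_scope: str = "thyroid"
    wc_threshold_maternal_umol: float = WC_THRESHOLD_MATERNAL_UMOL
    wc_threshold_fetal_umol: Optional[float] = None
    wc_duration_d: float = WC_DURATION_H / 24.0
    specific_activity_bq_per_g: float = I131_SPECIFIC_ACTIVITY_BQ_PER_G
    molar_mass_i131: float = MOLAR_MASS_I131
    molar_mass_stable: float = MOLAR_MASS_STABLE

    def flow(self, source: str, target: str) -> FlowSpec:
        """Return the unique flow between two compartments."""
        for f in self.flows:
            if f.source == source and f.target == target:
                return f
        raise KeyError(f"no flow {source} -> {target}")


def derive_mm(
    k: float, vd: float, km: float = KM_CONC_UMOL_PER_L
) -> tuple[float, float]:
    """Derive carrier parameters (Tmax, Km#) from a first-order constant.

    Parameters
    ----------
    k : linear-regime rate constant, d⁻¹ (k >= 0)
    vd : distribution volume of the source compartment, l (> 0)
    km : Michaelis constant as a concentration, µmol·l⁻¹ (> 0)

    Returns
    -------
    (tmax, km_abs) : maximum transport rate (µmol·d⁻¹) and the Michaelis
    constant expressed as an absolute amount (µmol).
    """
    if k < 0:
        raise ValueError("rate constant k must be non-negative")
    if vd <= 0 or km <= 0:
        raise ValueError("vd and km must be positive")
    return km * k * vd, km * vd


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("thyroblock.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def _read_manifest() -> dict:
    with resources.files("thyroblock.data").joinpath("flow_manifest.json").open() as fh:
        return json.load(fh)


def _week_col(week: int) -> str:
    return f"w{week}"


def _opt(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def fetal_wc_threshold(thyroid_weight_fetal_g: Optional[float]) -> Optional[float]:
    """Wolff–Chaikoff switch-on threshold for the fetal gland, µmol.

    No measured saturation amount exists for the fetal thyroid; the block is
    assumed to engage when the uptake reaches the same *fraction* (4.375 %)
    of the gland's iodine content as in the adult, with the fetal content
    estimated from the adult iodine concentration (500 µg per g of tissue)
    scaled by the fetal gland weight.
    """
    if thyroid_weight_fetal_g is None:
        return None
    content_ug = ADULT_GLAND_IODINE_UG_PER_G * thyroid_weight_fetal_g
    return WC_SATURATION_FRACTION * content_ug / MOLAR_MASS_STABLE


@lru_cache(maxsize=None)
def load_parameters(week: int) -> ModelParameters:
    """Load the full parameter set for one tabulated pregnancy week.

    Raises ``ValueError`` for weeks outside the tabulated set — the model is
    parametrised only at the published ages and does not interpolate.
    """
    if week not in SUPPORTED_WEEKS:
        raise ValueError(
            f"unsupported pregnancy week {week}; "
            f"parameters are tabulated for weeks {sorted(SUPPORTED_WEEKS)}"
        )
    col = _week_col(week)

    phys_df = _read_csv("physiology.csv").set_index("quantity")
    phys = Physiology(
        week=week,
        vd_maternal_blood_l=float(phys_df.at["vd_maternal_blood_l", col]),
        thyroid_weight_maternal_g=float(phys_df.at["thyroid_weight_maternal_g", col]),
        lobe_radius_maternal_cm=float(phys_df.at["lobe_radius_maternal_cm", col]),
        fetal_weight_g=_opt(phys_df.at["fetal_weight_g", col]),
        vd_fetal_l=_opt(phys_df.at["vd_fetal_l", col]),
        thyroid_weight_fetal_g=_opt(phys_df.at["thyroid_weight_fetal_g", col]),
        lobe_radius_fetal_cm=_opt(phys_df.at["lobe_radius_fetal_cm", col]),
    )

    manifest = _read_manifest()
    flow_map = manifest["flows"]
    skip_first_order = set(manifest.get("duplicate_of_carrier", ()))

    flows: list[FlowSpec] = []

    carrier = _read_csv("carrier_flows.csv")
    for label, grp in carrier.groupby("flow", sort=False):
        row = grp.set_index("param")[col]
        meta = flow_map[label]
        k = float(row["k"])
        flows.append(
            FlowSpec(
                name=label,
                source=meta["source"],
                target=meta["target"],
                law="michaelis_menten",
                k=k,
                km_abs=_opt(row["km_abs"]) if k > 0 else None,
                tmax=_opt(row["tmax"]) if k > 0 else None,
                wc_gated=bool(meta.get("wc_gated", False)),
                gland=meta.get("gland"),
            )
        )

    varying = _read_csv("firstorder_varying.csv")
    for _, row in varying.iterrows():
        meta = flow_map[row["flow"]]
        flows.append(
            FlowSpec(
                name=row["flow"],
                source=meta["source"],
                target=meta["target"],
                law="first_order",
                k=float(row[col]),
            )
        )

    constant = _read_csv("firstorder_constant.csv")
    for _, row in constant.iterrows():
        label = row["flow"]
        if label in skip_first_order:
            # linear-regime duplicate of a carrier-mediated flow
            continue
        meta = flow_map[label]
        flows.append(
            FlowSpec(
                name=label,
                source=meta["source"],
                target=meta["target"],
                law="first_order",
                k=float(row["k"]),
            )
        )

    return ModelParameters(
        week=week,
        physiology=phys,
        flows=tuple(flows),
        wc_threshold_fetal_umol=fetal_wc_threshold(phys.thyroid_weight_fetal_g),
    )


def validate_tables(carrier: pd.DataFrame | None = None) -> list[str]:
    """Consistency checks on the shipped parameter tables.

    Verifies for every active carrier flow and week that the printed Tmax
    and Km# satisfy Tmax = Km·k·Vd and Km# = Km·Vd (relative deviation
    < 1e-3, i.e. agreement with the printed 4-significant-figure values),
    that every compartment appears in the flow network, and that the fetal
    distribution volume is half the fetal weight.  Returns a list of
    violation messages (empty for the shipped data).  A replacement carrier
    table may be injected for testing.
    """
    problems: list[str] = []
    if carrier is None:
        carrier = _read_csv("carrier_flows.csv")
    phys = _read_csv("physiology.csv").set_index("quantity")
    flow_map = _read_manifest()["flows"]

    for week in SUPPORTED_WEEKS:
        col = _week_col(week)
        vd_blood = float(phys.at["vd_maternal_blood_l", col])
        vd_fetal = _opt(phys.at["vd_fetal_l", col])
        for label, grp in carrier.groupby("flow", sort=False):
            row = grp.set_index("param")[col]
            k = float(row["k"])
            if k == 0:
                continue
            source = flow_map[label]["source"]
            vd = vd_blood if source == "blood" else vd_fetal
            if vd is None:
                problems.append(f"{label} week {week}: active flow without Vd")
                continue
            tmax_expect, km_expect = derive_mm(k, vd)
            tmax, km_abs = float(row["tmax"]), float(row["km_abs"])
            if abs(tmax - tmax_expect) / tmax_expect > 1e-3:
                problems.append(
                    f"{label} week {week}: Tmax {tmax} != Km*k*Vd {tmax_expect:.6g}"
                )
            if abs(km_abs - km_expect) / km_expect > 1e-3:
                problems.append(
                    f"{label} week {week}: Km# {km_abs} != Km*Vd {km_expect:.6g}"
                )

        fw = _opt(phys.at["fetal_weight_g", col])
        if fw is not None and vd_fetal is not None:
            if abs(vd_fetal - 0.5 * fw / 1000.0) / vd_fetal > 1e-3:
                problems.append(f"week {week}: Vd_fetal != 50% of fetal weight")

    seen = {c for f in load_parameters(38).flows for c in (f.source, f.target)}
    for comp in COMPARTMENTS:
        if comp not in seen:
            problems.append(f"compartment {comp} appears in no flow")
    return problems
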