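"""Reaction quantitation and colony-screening statistics.

Covers the bench arithmetic around an isothermal assembly: molar/mass
conversions for dsDNA stocks (parts are normalized to 57 nM, so 1 uL
carries 5.7e-2 pmol), the standard reaction layout (15 uL master mix +
5 uL pooled inserts, 50 degC for 20 min, 200 ng backbone), and the number
of colonies to screen so that at least one is correct with a target
confidence — if each colony is independently correct with probability p,
screening n colonies succeeds with probability 1 - (1-p)^n.

Per-colony correct-assembly probabilities fall with fragment count; they
are construct- and prep-dependent, so :class:`EfficiencyTable` ships
empty and must be supplied by the user (or taken from
:data:`ILLUSTRATIVE_EFFICIENCIES`, a non-measured example consistent with
the three-colony / five-colony rules of thumb for two- and four-fragment
reactions at >99% confidence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import GmapError

#: Average molar mass of double-stranded DNA, anhydrous salt-free
#: convention: 617.96 g/mol per bp plus 36.04 g/mol for the ends.
DS_DNA_G_PER_MOL_PER_BP = 617.96
DS_DNA_G_PER_MOL_CONST = 36.04


@dataclass
class ReactionDefaults:
    """Protocol constants for one assembly reaction."""

    stock_conc: float = 57.0            # nM, normalized part stock
    insert_amount: float = 5.7e-2       # pmol per insert
    backbone_mass: float = 200.0        # ng
    master_mix_volume: float = 15.0     # uL
    insert_volume_total: float = 5.0    # uL, pooled inserts topped up with TE
    incubation_temp: float = 50.0       # degC
    incubation_min: float = 20.0        # minutes
    confidence: float = 0.99

    def __post_init__(self):
        positive = {
            "stock_conc": self.stock_conc,
            "insert_amount": self.insert_amount,
            "backbone_mass": self.backbone_mass,
            "master_mix_volume": self.master_mix_volume,
            "insert_volume_total": self.insert_volume_total,
            "incubation_min": self.incubation_min,
        }
        for k, v in positive.items():
            if v <= 0:
                raise GmapError(f"{k} must be strictly positive, got {v}")
        if not 0 < self.confidence < 1:
            raise GmapError(f"confidence must be in (0,1), got {self.confidence}")


@dataclass
class EfficiencyTable:
    """fragment count (excluding backbone) -> per-colony correct probability."""

    values: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        last = 1.0
        for n in sorted(self.values):
            p = self.values[n]
            if not 0 < p <= 1:
                raise GmapError(f"efficiency for {n} fragments must be in (0,1], got {p}")
            if p > last:
                raise GmapError(
                    "efficiency must be non-increasing in fragment count; "
                    f"{n} fragments has {p} > previous {last}"
                )
            last = p

    def get(self, n_fragments: int) -> float | None:
        return self.values.get(n_fragments)


#: Example efficiencies consistent with the published screening guidance;
#: not measured values — supply your own for real preps.
ILLUSTRATIVE_EFFICIENCIES = EfficiencyTable({1: 0.90, 2: 0.80, 3: 0.72, 4: 0.65})


def ds_dna_mass_for_amount(length: int, amount: float) -> float:
    """Mass (ng) of ``amount`` pmol of a ``length``-bp dsDNA.

    mass[ng] = amount[pmol] * (617.96*length + 36.04)[g/mol] * 1e-3
    """
    if length < 1:
        raise GmapError(f"length must be >= 1 bp, got {length}")
    if amount <= 0:
        raise GmapError(f"amount must be > 0 pmol, got {amount}")
    molar_mass = DS_DNA_G_PER_MOL_PER_BP * length + DS_DNA_G_PER_MOL_CONST
    return amount * molar_mass * 1e-3


def amount_in_volume(conc: float, volume: float) -> float:
    """pmol of DNA in ``volume`` uL of a ``conc`` nM stock (conc*vol*1e-3)."""
    if conc <= 0:
        raise GmapError(f"concentration must be > 0 nM, got {conc}")
    if volume <= 0:
        raise GmapError(f"volume must be > 0 uL, got {volume}")
    return conc * volume * 1e-3


def success_probability(p: float, n: int) -> float:
    """Probability that at least one of n colonies is correct: 1 - (1-p)^n."""
    if not 0 <= p <= 1:
        raise GmapError(f"p must be in [0,1], got {p}")
    if n < 0:
        raise GmapError(f"n must be >= 0, got {n}")
    return 1.0 - (1.0 - p) ** n


def colonies_to_screen(p: float, confidence: float = 0.99) -> int:
    """Smallest n with 1 - (1-p)^n strictly greater than ``confidence``.

    With per-colony efficiencies of 0.80 (two-fragment) and 0.65
    (four-fragment) at 99% confidence this gives the familiar "screen at
    least three" and "screen five" rules.
    """
    if not 0 < confidence < 1:
        raise GmapError(f"confidence must be in (0,1), got {confidence}")
    if p >= 1:
        return 1
    if p <= 0:
        raise GmapError(f"per-colony probability must be > 0, got {p}")
    n = math.floor(math.log(1.0 - confidence) / math.log(1.0 - p)) + 1
    # floating-point guard around the strict inequality
    while success_probability(p, n) <= confidence:
        n += 1
    while n > 1 and success_probability(p, n - 1) > confidence:
        n -= 1
    return n


#: The 5X isothermal buffer batch: (component, amount, final in the 6 mL).
FIVE_X_BUFFER_RECIPE = pd.DataFrame(
    [
        ("Tris-HCl pH 7.5", "3 mL of 1 M", "500 mM"),
        ("MgCl2", "300 uL of 1 M", "50 mM"),
        ("dNTPs", "600 uL of 10 mM", "1 mM"),
        ("DTT", "300 uL of 1 M", "50 mM"),
        ("PEG-8000", "1.5 g", "25 % w/v"),
        ("NAD", "20 mg", "3.33 mg/mL"),
        ("water", "up to 6 mL", ""),
    ],
    columns=["component", "amount", "final_concentration"],
)

#: One master-mix batch (1201.2 uL total; 15 uL per reaction).
MASTER_MIX_RECIPE = pd.DataFrame(
    [
        ("5X isothermal buffer", 320.0),
        ("T5 exonuclease", 1.2),
        ("Phusion polymerase", 20.0),
        ("Taq ligase", 160.0),
        ("water", 700.0),
    ],
    columns=["component", "volume_ul"],
)


@dataclass
class ReactionPlan:
    """Pipetting sheet + incubation + screening advice for one assembly."""

    components: pd.DataFrame       # name, length_bp, stock_nM, volume_uL, amount_pmol, mass_ng
    master_mix: pd.DataFrame
    buffer_recipe: pd.DataFrame
    incubation_temp: float
    incubation_min: float
    total_volume: float
    colonies_to_screen: int | None
    notes: list[str] = field(default_factory=list)

    def to_tsv(self) -> str:
        return self.components.to_csv(sep="\t", index=False, float_format="%.4g")


def reaction_plan(
    parts,
    backbone,
    defaults: ReactionDefaults | None = None,
    efficiency: EfficiencyTable | None = None,
) -> ReactionPlan:
    """Lay out one isothermal assembly for a list of insert Parts and a
    Backbone: per-insert volumes at the normalized stock, the backbone at
    its standard mass, master-mix and buffer recipes, and — when the
    efficiency table covers this fragment count — colonies to screen."""
    defaults = defaults or ReactionDefaults()
    parts = list(parts)
    if not parts:
        raise GmapError("need at least one insert part")
    rows = []
    per_insert_volume = defaults.insert_amount / defaults.stock_conc * 1e3  # uL
    for part in parts:
        length = len(part)
        rows.append(
            {
                "name": getattr(part, "name", "insert"),
                "length_bp": length,
                "stock_nM": defaults.stock_conc,
                "volume_uL": per_insert_volume,
                "amount_pmol": amount_in_volume(defaults.stock_conc, per_insert_volume),
                "mass_ng": ds_dna_mass_for_amount(length, defaults.insert_amount),
            }
        )
    bb_len = len(backbone)
    bb_molar_mass = DS_DNA_G_PER_MOL_PER_BP * bb_len + DS_DNA_G_PER_MOL_CONST
    bb_pmol = defaults.backbone_mass / bb_molar_mass * 1e3
    rows.append(
        {
            "name": getattr(backbone, "name", "backbone"),
            "length_bp": bb_len,
            "stock_nM": float("nan"),
            "volume_uL": float("nan"),
            "amount_pmol": bb_pmol,
            "mass_ng": defaults.backbone_mass,
        }
    )
    notes = []
    insert_vol = per_insert_volume * len(parts)
    if insert_vol > defaults.insert_volume_total:
        notes.append(
            f"pooled insert volume {insert_vol:.2f} uL exceeds the "
            f"{defaults.insert_volume_total} uL insert budget; concentrate stocks"
        )
    else:
        notes.append(
            f"top up inserts to {defaults.insert_volume_total} uL with TE buffer"
        )
    n_colonies = None
    if efficiency is not None:
        p = efficiency.get(len(parts))
        if p is not None:
            n_colonies = colonies_to_screen(p, defaults.confidence)
        else:
            notes.append(
                f"no efficiency known for {len(parts)} fragments; "
                "colonies-to-screen omitted"
            )
    else:
        notes.append("no efficiency table supplied; colonies-to-screen omitted")
    return ReactionPlan(
        components=pd.DataFrame(rows),
        master_mix=MASTER_MIX_RECIPE.copy(),
        buffer_recipe=FIVE_X_BUFFER_RECIPE.copy(),
        incubation_temp=defaults.incubation_temp,
        incubation_min=defaults.incubation_min,
        total_volume=defaults.master_mix_volume + defaults.insert_volume_total,
        colonies_to_screen=n_colonies,
        notes=notes,
    )
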