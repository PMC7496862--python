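"""Clinical utilities: MDRD eGFR, risk-band classification, colour scale.

Band boundaries follow the KDIGO-style conventions used in transplant
follow-up: proteinuria physiological/light/moderate/severe/nephrotic at
150/500/1000/3000 mg/24 h, CKD stages 1-5 at GFR 90/60/30/15 mL/min.
Exact proteinuria boundary values belong to the higher-risk band
(protective reading); GFR stage intervals are lower-inclusive,
matching the printed "30 <= GFR < 60" pattern, so GFR = 15 is stage 4.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RiskBand",
    "PROTEINURIA_RISK_BANDS",
    "GFR_RISK_BANDS",
    "COLOR_SCALE",
    "mdrd_gfr",
    "proteinuria_band",
    "gfr_stage",
    "risk_color",
]

COLOR_SCALE = ("green", "yellow-green", "yellow", "orange", "red")


@dataclass(frozen=True)
class RiskBand:
    """One risk category on a five-point green-to-red scale."""

    label: str          # FIS output term / stage label
    clinical_name: str  # physician-facing name
    ordinal: int        # 0 (no risk) .. 4 (high risk)

    def __post_init__(self) -> None:
        if not 0 <= self.ordinal <= 4:
            raise ValueError("risk ordinal must be in 0..4")

    @property
    def color(self) -> str:
        return COLOR_SCALE[self.ordinal]


PROTEINURIA_RISK_BANDS = (
    RiskBand("good", "physiological proteinuria", 0),
    RiskBand("sufficient", "light proteinuria", 1),
    RiskBand("alterate", "moderate proteinuria", 2),
    RiskBand("alarm", "severe proteinuria", 3),
    RiskBand("danger", "nephrotic proteinuria", 4),
)

GFR_RISK_BANDS = (
    RiskBand("good", "stage 1", 0),
    RiskBand("alarm2", "stage 2", 1),
    RiskBand("alarm3", "stage 3", 2),
    RiskBand("alarm4", "stage 4", 3),
    RiskBand("danger", "stage 5", 4),
)

# Upper edges of the proteinuria bands (mg/24 h); boundary -> higher risk.
_PROTEINURIA_EDGES = (150.0, 500.0, 1000.0, 3000.0)
# Lower edges of GFR stages 1..4 (mL/min); lower-inclusive.
_GFR_EDGES = (90.0, 60.0, 30.0, 15.0)


def mdrd_gfr(
    serum_creatinine: float,
    age: float,
    sex: str,
    black: bool = False,
    coefficient: float = 175.0,
) -> float:
    """Estimated GFR (mL/min/1.73 m2) by the 4-variable MDRD equation.

    ``coefficient`` is 175 for the IDMS-traceable re-expressed form
    (default) or 186 for the legacy form.  ``sex`` is ``"M"``/``"F"``
    (case-insensitive; ``"male"``/``"female"`` accepted).
    """
    if serum_creatinine <= 0:
        raise ValueError("serum creatinine must be positive")
    if age <= 0:
        raise ValueError("age must be positive")
    s = sex.strip().upper()[:1]
    if s not in ("M", "F"):
        raise ValueError(f"sex must be male or female, got {sex!r}")
    gfr = coefficient * serum_creatinine ** -1.154 * age ** -0.203
    if s == "F":
        gfr *= 0.742
    if black:
        gfr *= 1.212
    return gfr


def proteinuria_band(value: float) -> RiskBand:
    """Crisp risk band of a 24-h proteinuria value (mg/24 h)."""
    if value < 0:
        raise ValueError("proteinuria cannot be negative")
    for band, edge in zip(PROTEINURIA_RISK_BANDS, _PROTEINURIA_EDGES):
        if value < edge:
            return band
    return PROTEINURIA_RISK_BANDS[-1]


def gfr_stage(value: float) -> RiskBand:
    """CKD stage of a GFR value (mL/min); stage intervals lower-inclusive."""
    if value < 0:
        raise ValueError("GFR cannot be negative")
    for band, edge in zip(GFR_RISK_BANDS, _GFR_EDGES):
        if value >= edge:
            return band
    return GFR_RISK_BANDS[-1]


def risk_color(band: RiskBand) -> str:
    """Colour label of a band on the five-point green-to-red scale."""
    return band.color


def band_function(output_kind: str):
    """Band classifier for an output kind (``"proteinuria"`` or ``"gfr"``)."""
    if output_kind == "proteinuria":
        return proteinuria_band
    if output_kind == "gfr":
        return gfr_stage
    raise ValueError(f"unknown output kind {output_kind!r}")
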