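"""Reconstitution arithmetic for type- and Hct-matched blood mixtures.

Artificial samples with a prescribed sickle-hemoglobin fraction are made by
combining blood from an SCA donor (genotype HbSS) with blood from a normal
donor (HbAA).  Because %HbS is a fraction of *total hemoglobin*, the mixture
fraction is the Hb-mass-weighted mean of the component fractions:

    %HbS = ([Hb]_SS · V_SS · %HbS_SS) / ([Hb]_SS · V_SS + [Hb]_AA · V_AA)

with the HbAA component contributing no HbS.  Units: [Hb] in g/dL, V in µL;
only the products enter, so any consistent unit pair works.

Hematocrit matching is done physically (by centrifugation) before mixing and
is carried here as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DegenerateInputError, InfeasibleTargetError, ValidationError

#: The study's default reconstitution targets, %HbS of total Hb.
DEFAULT_TARGET_LEVELS: tuple[float, ...] = (0.0, 10.0, 20.0, 40.0, 80.0)

#: Physiological hematocrit for SCA used when matching components, %.
DEFAULT_HEMATOCRIT_PERCENT: float = 22.0


@dataclass(frozen=True)
class BloodComponent:
    """One constituent of a reconstituted sample.

    Parameters
    ----------
    hb_concentration : float
        Total hemoglobin concentration [Hb], g/dL.
    volume : float
        Volume V, µL.
    hbs_percent : float
        Percentage of this component's hemoglobin that is HbS (0–100).
    """

    hb_concentration: float
    volume: float
    hbs_percent: float = 0.0

    def __post_init__(self) -> None:
        if not self.hb_concentration > 0:
            raise ValidationError("hb_concentration must be > 0")
        if self.volume < 0:
            raise ValidationError("volume must be >= 0")
        if not 0.0 <= self.hbs_percent <= 100.0:
            raise ValidationError("hbs_percent must lie in [0, 100]")

    @property
    def hb_mass(self) -> float:
        """[Hb] · V, the component's total hemoglobin mass (arbitrary units)."""
        return self.hb_concentration * self.volume


@dataclass(frozen=True)
class MixtureSpec:
    """A two-component reconstitution: SCA donor blood plus normal donor blood."""

    hbss_component: BloodComponent
    hbaa_component: BloodComponent
    hematocrit_percent: float = DEFAULT_HEMATOCRIT_PERCENT

    def __post_init__(self) -> None:
        if self.hbss_component.hbs_percent <= 0:
            raise ValidationError("HbSS component must have hbs_percent > 0")
        if self.hbaa_component.hbs_percent != 0:
            raise ValidationError("HbAA component must have hbs_percent == 0")
        if self.hbss_component.volume == 0 and self.hbaa_component.volume == 0:
            raise ValidationError("at least one component volume must be > 0")


def percent_hbs(mix: MixtureSpec) -> float:
    """%HbS of a reconstituted mixture (Hb-mass-weighted mean of components).

    Raises
    ------
    DegenerateInputError
        If both component Hb masses are zero (no hemoglobin in the mixture).
    """
    m_ss = mix.hbss_component.hb_mass
    m_aa = mix.hbaa_component.hb_mass
    denom = m_ss + m_aa
    if denom <= 0:
        raise DegenerateInputError("mixture contains no hemoglobin")
    return (
        m_ss * mix.hbss_component.hbs_percent
        + m_aa * mix.hbaa_component.hbs_percent
    ) / denom


def solve_volume_ratio(
    target_hbs_percent: float,
    hbss: BloodComponent,
    hbaa: BloodComponent,
) -> float:
    """Volume ratio V_SS / V_AA that reconstitutes ``target_hbs_percent``.

    Inverting the mixture equation for the volume ratio r = V_SS / V_AA gives

        r = ([Hb]_AA · target) / ([Hb]_SS · (%HbS_SS − target))

    The target must be strictly below the SCA component's own %HbS; equality
    would require no HbAA blood at all (infinite ratio).
    """
    if target_hbs_percent < 0:
        raise InfeasibleTargetError("target %HbS must be non-negative")
    if target_hbs_percent >= hbss.hbs_percent:
        raise InfeasibleTargetError(
            f"target {target_hbs_percent}% is not below the SCA component's "
            f"{hbss.hbs_percent}% HbS"
        )
    return (hbaa.hb_concentration * target_hbs_percent) / (
        hbss.hb_concentration * (hbss.hbs_percent - target_hbs_percent)
    )


def mixture_for_target(
    target_hbs_percent: float,
    hbss: BloodComponent,
    hbaa: BloodComponent,
    total_volume: float = 1000.0,
    hematocrit_percent: float = DEFAULT_HEMATOCRIT_PERCENT,
) -> MixtureSpec:
    """Build a :class:`MixtureSpec` hitting ``target_hbs_percent`` at a total volume."""
    if target_hbs_percent == 0:
        v_ss, v_aa = 0.0, total_volume
    else:
        r = solve_volume_ratio(target_hbs_percent, hbss, hbaa)
        v_aa = total_volume / (1.0 + r)
        v_ss = total_volume - v_aa
    return MixtureSpec(
        hbss_component=BloodComponent(hbss.hb_concentration, v_ss, hbss.hbs_percent),
        hbaa_component=BloodComponent(hbaa.hb_concentration, v_aa, 0.0),
        hematocrit_percent=hematocrit_percent,
    )
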