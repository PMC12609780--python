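"""Ocular-magnification correction and pixel-to-mm² conversion.

En-face OCTA angiograms are acquired over a nominally fixed retinal field
(3 × 3 mm spanned by a fixed number of pixels), but the true retinal extent
of the scan depends on the eye's axial length (AL): longer eyes magnify the
retinal image. The modified Bennett correction rescales the nominal image
scale by the ratio of the measured AL to the reference AL assumed by the
device, and FAZ pixel counts are converted to mm² with the square of the
corrected scale.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ScalingConfig",
    "magnification_factor",
    "corrected_scale",
    "area_mm2",
    "AL_RANGE_MM",
]

#: Admissible axial-length range (mm); values outside are treated as data errors.
AL_RANGE_MM = (15.0, 40.0)


@dataclass(frozen=True)
class ScalingConfig:
    """Acquisition-geometry constants used for the magnification correction.

    Parameters
    ----------
    field_mm : float
        Nominal scan field width in mm.
    nominal_px : int
        Number of pixels spanning the nominal field.
    reference_al_mm : float
        Axial length (mm) assumed by the device when it reports the nominal
        scale; an emmetropic reference eye.
    use_bennett_q : bool
        If True, use the full Littmann–Bennett q-ratio
        ``q = 0.01306 (AL − 1.82)`` instead of the plain AL ratio.  The plain
        ratio is the default operational form; the q-ratio variant is kept
        for sensitivity analyses.
    """

    field_mm: float = 3.0
    nominal_px: int = 510
    reference_al_mm: float = 23.95
    use_bennett_q: bool = False

    def __post_init__(self) -> None:
        if self.field_mm <= 0 or self.nominal_px <= 0 or self.reference_al_mm <= 0:
            raise ValueError("field_mm, nominal_px and reference_al_mm must be positive")


_DEFAULT = ScalingConfig()


def _check_al(al_mm: float) -> None:
    lo, hi = AL_RANGE_MM
    if not (lo < al_mm < hi):
        raise ValueError(
            f"axial length {al_mm!r} mm outside the admissible range ({lo}, {hi}) mm"
        )


def magnification_factor(al_mm: float, cfg: ScalingConfig = _DEFAULT) -> float:
    """Relative ocular magnification of an eye with axial length ``al_mm``.

    With the default (plain-ratio) form this is simply
    ``al_mm / cfg.reference_al_mm``: 1.0 for the reference eye, >1 for
    longer eyes.
    """
    _check_al(al_mm)
    if cfg.use_bennett_q:
        return (0.01306 * (al_mm - 1.82)) / (0.01306 * (cfg.reference_al_mm - 1.82))
    return al_mm / cfg.reference_al_mm


def corrected_scale(al_mm: float, cfg: ScalingConfig = _DEFAULT) -> float:
    """Magnification-corrected image scale in mm per pixel."""
    return (cfg.field_mm / cfg.nominal_px) * magnification_factor(al_mm, cfg)


def area_mm2(pixel_count: int, al_mm: float, cfg: ScalingConfig = _DEFAULT) -> float:
    """Convert a FAZ pixel count to a retinal area in mm².

    The corrected linear scale is squared, so the area grows with
    ``(AL / reference AL)²``.
    """
    if pixel_count < 0:
        raise ValueError("pixel_count must be nonnegative")
    return float(pixel_count) * corrected_scale(al_mm, cfg) ** 2
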