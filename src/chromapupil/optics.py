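"""Schematic-eye geometry for ring-light stimulus design.

Chromatic pupillometry aimed at the melanopsin-bearing ipRGCs benefits from
a stimulus that lands on the perifovea, the annular retinal region (here
1.25-2.75 mm from the foveal centre) where those cells are densest and which
excludes the fovea.  A ring of LEDs placed coaxially in front of the eye does
exactly that if its diameter and viewing distance are chosen so that the chief
ray of each LED crosses the eye's nodal point and lands inside the annulus.

The model here is the reduced schematic eye: a single refracting surface with
all chief rays passing undeviated through one nodal point located a fixed
posterior nodal distance (PND) in front of the retina.  A point source offset
laterally by ``x`` at distance ``d`` subtends ``tan(theta) = x / d`` at the
nodal point, so its retinal image sits at eccentricity

    e = PND * (x / d)

from the foveal centre (lengths on the object side in cm, retinal lengths in
mm).  The default PND of 16.67 mm is Emsley's reduced eye.  The same formula,
fed with the effective lateral offset of an off-axis ambient lamp, checks that
the ambient illumination used to keep the video exposed does *not* reach the
perifovea.

The pupil aperture is carried for documentation and blur estimates only: in a
nodal-ray model the aperture widens the retinal spot but does not move its
centroid, which is the quantity designed for here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import GeometryError

__all__ = [
    "SchematicEyeModel",
    "RingStimulusGeometry",
    "PerifovealBand",
    "RingLanding",
    "EMSLEY_REDUCED_EYE",
    "retinal_eccentricity",
    "ring_landing_annulus",
    "ring_diameter_for_eccentricity",
    "source_in_band",
]

MM_PER_CM = 10.0

#: Dominant LED wavelengths (nm) by stimulus colour.  Blue and red follow the
#: OSTAMC5B32A datasheet (470 +/- 5, 625 +/- 5); green is a nominal mid-green.
NOMINAL_WAVELENGTH_NM = {"blue": 470.0, "red": 625.0, "green": 525.0}


@dataclass(frozen=True)
class SchematicEyeModel:
    """Reduced schematic eye parameterised by its posterior nodal distance.

    Parameters
    ----------
    posterior_nodal_distance_mm:
        Distance from the nodal point to the retina, mm.  16.67 mm is the
        Emsley reduced eye.
    axial_length_mm:
        Overall axial length, mm; must be at least the nodal distance.
    pupil_aperture_mm:
        Bright-light pupil diameter, mm (2 mm is the minimum normal photopic
        pupil).  Informational in the chief-ray model.
    """

    posterior_nodal_distance_mm: float = 16.67
    axial_length_mm: float = 22.22
    pupil_aperture_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.posterior_nodal_distance_mm <= 0:
            raise GeometryError("posterior_nodal_distance_mm must be positive")
        if self.pupil_aperture_mm <= 0:
            raise GeometryError("pupil_aperture_mm must be positive")
        if self.axial_length_mm < self.posterior_nodal_distance_mm:
            raise GeometryError(
                "axial_length_mm must be >= posterior_nodal_distance_mm"
            )


EMSLEY_REDUCED_EYE = SchematicEyeModel()


@dataclass(frozen=True)
class PerifovealBand:
    """Annulus of retinal eccentricities (mm) targeted by the ring stimulus."""

    inner_radius_mm: float = 1.25
    outer_radius_mm: float = 2.75

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius_mm < self.outer_radius_mm:
            raise GeometryError("need 0 < inner_radius_mm < outer_radius_mm")

    def contains(self, eccentricity_mm: float) -> bool:
        return self.inner_radius_mm <= eccentricity_mm <= self.outer_radius_mm


@dataclass(frozen=True)
class RingStimulusGeometry:
    """A ring-light stimulus: physical ring plus colour and drive level."""

    ring_diameter_cm: float
    eye_distance_cm: float = 15.0
    color: str = "blue"
    nominal_wavelength_nm: float | None = None
    intensity_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.ring_diameter_cm < 0:
            raise GeometryError("ring_diameter_cm must be non-negative")
        if self.eye_distance_cm <= 0:
            raise GeometryError("eye_distance_cm must be positive")
        if not 0.0 <= self.intensity_fraction <= 1.0:
            raise GeometryError("intensity_fraction must lie in [0, 1]")
        if self.color not in NOMINAL_WAVELENGTH_NM:
            raise GeometryError(f"unknown stimulus color {self.color!r}")
        if self.nominal_wavelength_nm is None:
            object.__setattr__(
                self, "nominal_wavelength_nm", NOMINAL_WAVELENGTH_NM[self.color]
            )


@dataclass(frozen=True)
class RingLanding:
    """Where a ring stimulus lands on the retina, against the target band."""

    eccentricity_mm: float
    in_band: bool
    band: PerifovealBand = field(default_factory=PerifovealBand)


def retinal_eccentricity(
    source_offset_cm: float,
    eye_distance_cm: float,
    eye: SchematicEyeModel = EMSLEY_REDUCED_EYE,
) -> float:
    """Retinal eccentricity (mm) of a point source's nodal chief ray.

    ``e = PND * offset / distance`` — the exact tangent of the chief-ray
    angle scaled by the posterior nodal distance.  Strictly increasing in
    the source offset and invariant under joint rescaling of offset and
    distance.
    """
    if eye_distance_cm <= 0:
        raise GeometryError("eye_distance_cm must be positive")
    if source_offset_cm < 0:
        raise GeometryError("source_offset_cm must be non-negative")
    return eye.posterior_nodal_distance_mm * (source_offset_cm / eye_distance_cm)


def ring_landing_annulus(
    ring: RingStimulusGeometry,
    eye: SchematicEyeModel = EMSLEY_REDUCED_EYE,
    band: PerifovealBand | None = None,
) -> RingLanding:
    """Eccentricity at which a ring stimulus lands, and whether it is in band.

    The ring's chief rays all share the same offset (the ring radius), so a
    single eccentricity characterises the landing annulus' centre.
    """
    band = PerifovealBand() if band is None else band
    ecc = retinal_eccentricity(ring.ring_diameter_cm / 2.0, ring.eye_distance_cm, eye)
    return RingLanding(eccentricity_mm=ecc, in_band=band.contains(ecc), band=band)


def ring_diameter_for_eccentricity(
    target_mm: float,
    eye_distance_cm: float = 15.0,
    eye: SchematicEyeModel = EMSLEY_REDUCED_EYE,
) -> float:
    """Ring diameter (cm) whose landing annulus sits at ``target_mm``.

    Exact inverse of :func:`retinal_eccentricity` applied to the ring radius.
    """
    if target_mm < 0:
        raise GeometryError("target_mm must be non-negative")
    if eye_distance_cm <= 0:
        raise GeometryError("eye_distance_cm must be positive")
    radius_cm = eye_distance_cm * target_mm / eye.posterior_nodal_distance_mm
    return 2.0 * radius_cm


def source_in_band(
    source_offset_cm: float,
    eye_distance_cm: float,
    eye: SchematicEyeModel = EMSLEY_REDUCED_EYE,
    band: PerifovealBand | None = None,
) -> bool:
    """Whether an off-axis source (e.g. a tilted ambient lamp) hits the band.

    Ambient illumination should return ``False``: it must light the eye for
    the camera without stimulating the perifoveal ipRGCs.
    """
    band = PerifovealBand() if band is None else band
    return band.contains(retinal_eccentricity(source_offset_cm, eye_distance_cm, eye))
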