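"""Reference 30 MHz Love-wave sensor design shipped with the package.

A LiNbO3 36Y-X substrate (isotropic-equivalent shear constants), 10 nm Cr +
165 nm Au metallization, an 8 um SU-8 guiding layer (z = h/lambda ~ 0.056),
12-finger IDTs with a 144 um period, 21-lambda aperture and a 37-lambda
delay path, probed with 50-ohm instrumentation.  The calibration liquids are
glycerol-water mixtures at 25 C spanning 0.893-4 cP.
"""

from __future__ import annotations

from .idt import DelayLineDesign, IDTDesign, SubstrateElectrical
from .materials import load_material
from .tlm import Layer, LayerStack

__all__ = [
    "reference_stack",
    "reference_delay_line",
    "calibration_liquids",
    "wetted_path",
    "WAVELENGTH",
    "GUIDING_LAYER_THICKNESS",
    "DELAY_PATH_WAVELENGTHS",
    "SENSING_PATH_WAVELENGTHS",
]

WAVELENGTH = 144e-6                 # IDT period, m
GUIDING_LAYER_THICKNESS = 8e-6      # SU-8, m
DELAY_PATH_WAVELENGTHS = 37         # centre-to-centre; 29 is a documented alternate
SENSING_PATH_WAVELENGTHS = 14       # metallized region wetted by the fluidic chamber


def reference_stack(top: str = "vacuum", guiding_thickness: float = GUIDING_LAYER_THICKNESS,
                    include_metal: bool = True) -> LayerStack:
    """The reference layer stack with a chosen top half-space.

    ``top`` is a library material name ("vacuum", "water_25C",
    "glycerol_4cP", ...).  ``include_metal=False`` drops the Cr/Au films,
    leaving SU-8 directly on the substrate (the two configurations bracket
    the ambiguity of whether the metallized sensing path loads the guide).
    """
    layers = []
    if include_metal:
        layers += [Layer(load_material("Cr"), 10e-9), Layer(load_material("Au"), 165e-9)]
    layers.append(Layer(load_material("SU8"), guiding_thickness))
    return LayerStack(load_material("LiNbO3_36YX_isotropic"), tuple(layers),
                      load_material(top))


def reference_delay_line(delay_wavelengths: float = DELAY_PATH_WAVELENGTHS) -> DelayLineDesign:
    """The 12-finger, 144 um, 21-lambda-aperture delay line on 50 ohms.

    Conversion losses follow the plain cross-field model (no extra
    bidirectionality term), which is how the reference device's reported
    model levels are defined; set ``include_bidirectionality=True`` on the
    returned design's replacement to add 3 dB per transducer.
    """
    idt = IDTDesign(finger_count=12, wavelength=WAVELENGTH, aperture=21 * WAVELENGTH)
    return DelayLineDesign(
        input_idt=idt,
        output_idt=idt,
        delay_path=delay_wavelengths * WAVELENGTH,
        electrical=SubstrateElectrical(),
        source_impedance=50.0,
        include_bidirectionality=False,
    )


def wetted_path() -> float:
    """Length of the liquid-covered sensing region in metres (14 lambda)."""
    return SENSING_PATH_WAVELENGTHS * WAVELENGTH


def calibration_liquids() -> list[tuple[float, float]]:
    """(viscosity Pa*s, density kg/m^3) of the five calibration liquids at 25 C."""
    names = ["water_25C", "glycerol_1.8cP", "glycerol_2.5cP",
             "glycerol_3.3cP", "glycerol_4cP"]
    out = []
    for n in names:
        m = load_material(n)
        out.append((m.viscosity, m.density))
    return out
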