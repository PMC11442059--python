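"""Predator visual systems: pigment templates, oil-droplet filtering, noise.

Three systems are bundled: a tetrachromatic UV-sensitive bird, a
tetrachromatic UV-sensitive lizard with oil-droplet-filtered cones, and a
dichromatic crab. Receptor noise follows the receptor-noise-limited rule
e_i = omega_ref * sqrt(eta_ref / eta_i), anchored at a named reference
receptor whose Weber fraction is quoted directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .spectra import GRID, Spectrum


@dataclass(frozen=True)
class Receptor:
    name: str
    lambda_max: float
    oil_cutoff: float | None = None
    rel_density: float = 1.0

    def __post_init__(self):
        if not (300.0 <= self.lambda_max <= 700.0):
            raise ValueError(f"receptor {self.name}: lambda_max {self.lambda_max} out of range")
        if self.rel_density <= 0:
            raise ValueError(f"receptor {self.name}: rel_density must be > 0")


def pigment_template(lambda_max: float, grid: np.ndarray = GRID) -> Spectrum:
    """Vitamin-A1 rhodopsin absorbance nomogram (alpha + beta band),
    peak-normalized to 1 on the grid.
    """
    if not (330.0 <= lambda_max <= 700.0):
        raise ValueError(f"lambda_max {lambda_max} outside supported range [330, 700]")
    lam = np.asarray(grid, dtype=float)
    x = lambda_max / lam
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lam_beta = 189.0 + 0.315 * lambda_max
    b = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((lam - lam_beta) / b) ** 2))
    s = alpha + beta
    s = s / s.max()
    return Spectrum(lam.copy(), s, role="irradiance", label=f"A1({lambda_max:g})")


def oil_droplet_filter(sensitivity: Spectrum, cutoff: float, slope: float = 0.04) -> Spectrum:
    """Apply a logistic long-pass oil-droplet transmission and re-normalize.

    T(lambda) = 1 / (1 + exp(-slope * (lambda - cutoff))); T(cutoff) = 0.5.
    """
    lam = sensitivity.wavelengths_nm
    t = 1.0 / (1.0 + np.exp(-slope * (lam - cutoff)))
    vals = sensitivity.values * t
    vals = vals / vals.max()
    return Spectrum(lam.copy(), vals, role=sensitivity.role, label=sensitivity.label)


@dataclass
class VisualSystem:
    """Receptor set with noise and luminance-channel definitions.

    ``luminance_rule`` is either ``{"mode": "single", "lambda_max": nm}``
    (a dedicated luminance receptor, e.g. avian double cones) or
    ``{"mode": "summed", "receptors": [names]}`` (summed quantum catches).
    """

    name: str
    receptors: list[Receptor]
    weber_chromatic: float
    weber_reference: str
    luminance_rule: dict
    weber_luminance: float
    oil_slope: float = 0.04
    sensitivities: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    luminance_sensitivity: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.receptors) not in (2, 4):
            raise ValueError("chromatic receptor count must be 2 or 4")
        if self.weber_reference not in {r.name for r in self.receptors}:
            raise ValueError(f"unknown reference receptor {self.weber_reference!r}")
        if not self.sensitivities:
            self._build_curves()

    def _build_curves(self) -> None:
        for r in self.receptors:
            s = pigment_template(r.lambda_max)
            if r.oil_cutoff is not None:
                s = oil_droplet_filter(s, r.oil_cutoff, slope=self.oil_slope)
            self.sensitivities[r.name] = s.values
        rule = self.luminance_rule
        if rule["mode"] == "single":
            self.luminance_sensitivity = pigment_template(rule["lambda_max"]).values
        elif rule["mode"] == "summed":
            for name in rule["receptors"]:
                if name not in self.sensitivities:
                    raise ValueError(f"luminance rule names unknown receptor {name!r}")
            self.luminance_sensitivity = None
        else:
            raise ValueError(f"unknown luminance rule mode {rule['mode']!r}")

    @property
    def receptor_names(self) -> list[str]:
        return [r.name for r in self.receptors]

    @property
    def n_receptors(self) -> int:
        return len(self.receptors)

    def densities(self) -> np.ndarray:
        return np.array([r.rel_density for r in self.receptors])

    def noise(self) -> np.ndarray:
        """Per-receptor noise e_i = omega_ref * sqrt(eta_ref / eta_i)."""
        eta = self.densities()
        eta_ref = eta[self.receptor_names.index(self.weber_reference)]
        return self.weber_chromatic * np.sqrt(eta_ref / eta)

    def sensitivity_matrix(self) -> np.ndarray:
        """(n_receptors, n_wavelengths) stack of sensitivity curves."""
        return np.stack([self.sensitivities[n] for n in self.receptor_names])

    # --- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "receptors": [
                {
                    "name": r.name,
                    "lambda_max": r.lambda_max,
                    "oil_cutoff": r.oil_cutoff,
                    "rel_density": r.rel_density,
                }
                for r in self.receptors
            ],
            "weber_chromatic": self.weber_chromatic,
            "weber_reference": self.weber_reference,
            "luminance_rule": self.luminance_rule,
            "weber_luminance": self.weber_luminance,
            "oil_slope": self.oil_slope,
        }

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "VisualSystem":
        receptors = [Receptor(**r) for r in d["receptors"]]
        return cls(
            name=d["name"],
            receptors=receptors,
            weber_chromatic=d["weber_chromatic"],
            weber_reference=d["weber_reference"],
            luminance_rule=d["luminance_rule"],
            weber_luminance=d["weber_luminance"],
            oil_slope=d.get("oil_slope", 0.04),
        )

    @classmethod
    def from_yaml(cls, text_or_path: str | Path) -> "VisualSystem":
        p = Path(text_or_path)
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls.from_dict(yaml.safe_load(text))


def build_bird_system() -> VisualSystem:
    """Average avian UV-sensitive tetrachromat; double-cone luminance channel."""
    return VisualSystem(
        name="bird",
        receptors=[
            Receptor("UVS", 370.0, rel_density=1.0),
            Receptor("SWS", 458.0, rel_density=1.9),
            Receptor("MWS", 547.0, rel_density=2.7),
            Receptor("LWS", 600.0, rel_density=2.7),
        ],
        weber_chromatic=0.1,
        weber_reference="LWS",
        luminance_rule={"mode": "single", "lambda_max": 563.0},
        weber_luminance=0.05,
    )


def build_lizard_system() -> VisualSystem:
    """Anoline-type UV-sensitive tetrachromat with oil-droplet-filtered cones;
    luminance from the summed catches of the two longest-wavelength receptors.
    """
    return VisualSystem(
        name="lizard",
        receptors=[
            Receptor("UVS", 370.0, oil_cutoff=330.0, rel_density=1.0),
            Receptor("SWS", 495.0, oil_cutoff=371.0, rel_density=1.0),
            Receptor("MWS", 550.0, oil_cutoff=463.0, rel_density=1.0),
            Receptor("LWS", 590.0, oil_cutoff=507.0, rel_density=3.0),
        ],
        weber_chromatic=0.05,
        weber_reference="LWS",
        luminance_rule={"mode": "summed", "receptors": ["MWS", "LWS"]},
        weber_luminance=0.05,
    )


def build_crab_system() -> VisualSystem:
    """Dichromatic non-UV crab; luminance from both receptors summed."""
    return VisualSystem(
        name="crab",
        receptors=[
            Receptor("SWS", 430.0, rel_density=1.0),
            Receptor("LWS", 590.0, rel_density=2.0),
        ],
        weber_chromatic=0.12,
        weber_reference="LWS",
        luminance_rule={"mode": "summed", "receptors": ["SWS", "LWS"]},
        weber_luminance=0.12,
    )


BUILDERS = {
    "bird": build_bird_system,
    "lizard": build_lizard_system,
    "crab": build_crab_system,
}


def forest_shade_irradiance(grid: np.ndarray = GRID) -> Spectrum:
    """Bundled forest-shade-like illuminant: relative photon flux, green-
    shifted, attenuated below 400 nm, positive everywhere, max-normalized.
    A measured illuminant should be supplied for real-data work.
    """
    lam = np.asarray(grid, dtype=float)
    base = np.exp(-0.5 * ((lam - 550.0) / 110.0) ** 2)
    uv_cut = 1.0 / (1.0 + np.exp(-(lam - 410.0) / 22.0))
    vals = base * (0.12 + 0.88 * uv_cut)
    vals = vals / vals.max()
    return Spectrum(lam.copy(), vals, role="irradiance", label="forest_shade")


def load_illuminant(path: str | Path) -> Spectrum:
    """Load a user-supplied illuminant from a wide CSV (wavelength, irradiance)."""
    import pandas as pd

    df = pd.read_csv(path)
    return Spectrum(
        df.iloc[:, 0].to_numpy(dtype=float),
        df.iloc[:, 1].to_numpy(dtype=float),
        role="irradiance",
        label=str(df.columns[1]),
    )
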