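"""Synthetic study generator: reflectance spectra and LMM-structured contrast
tables with the layout of the field design (9 localities x 8 males x 4 dorsal
reads; 3 substrate types x 6 reads per object per locality).

Red dorsa are modeled as a long-pass reflectance edge, green dorsa as a
mid-wavelength Gaussian band; both carry an individual offset and per-read
measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mmi import MAINS, ModelSpec, design_matrix
from .spectra import GRID, Spectrum, SpectrumSet
from .visual import forest_shade_irradiance

#: (name, species, morph) for the default nine localities
DEFAULT_LOCALITIES: tuple[tuple[str, str, str], ...] = (
    ("DAM", "granulifera", "green"),
    ("ESQ", "granulifera", "green"),
    ("SAN", "granulifera", "red"),
    ("PAL", "granulifera", "red"),
    ("HIT", "pumilio", "red"),
    ("ALM", "pumilio", "red"),
    ("BAS", "pumilio", "red"),
    ("CAY", "pumilio", "green"),
    ("POP", "pumilio", "green"),
)

SUBSTRATE_TYPES = ("green_leaf", "leaf_litter", "trunk")


@dataclass
class StudyDesign:
    localities: tuple[tuple[str, str, str], ...] = DEFAULT_LOCALITIES
    n_males_per_locality: int = 8
    n_dorsal_reads: int = 4
    substrate_types: tuple[str, ...] = SUBSTRATE_TYPES
    n_substrate_reads: int = 6
    seed: int = 0

    @property
    def n_individuals(self) -> int:
        return len(self.localities) * self.n_males_per_locality


@dataclass
class MorphSpectralParams:
    red_edge_nm: float = 590.0
    red_steepness_nm: float = 30.0
    red_plateau: float = 0.55
    green_center_nm: float = 550.0
    green_width_nm: float = 45.0
    green_amplitude: float = 0.45
    baseline: float = 0.12
    individual_sd: float = 0.02
    measurement_sd: float = 0.005


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_frog_spectrum(
    morph: str,
    params: MorphSpectralParams,
    rng: np.random.Generator,
    individual_offset: float = 0.0,
    label: str = "",
) -> Spectrum:
    """One dorsal reflectance read for a red or green morph."""
    lam = GRID
    if morph == "red":
        shape = params.baseline + params.red_plateau * _logistic(
            (lam - params.red_edge_nm) / params.red_steepness_nm
        )
    elif morph == "green":
        shape = params.baseline + params.green_amplitude * np.exp(
            -((lam - params.green_center_nm) ** 2) / (2.0 * params.green_width_nm**2)
        )
    else:
        raise ValueError(f"unknown morph {morph!r}")
    vals = shape + individual_offset + rng.normal(0.0, params.measurement_sd, size=lam.shape)
    return Spectrum(lam.copy(), np.clip(vals, 0.0, 1.0), role="reflectance", label=label)


def make_background_spectrum(
    type: str, rng: np.random.Generator, measurement_sd: float = 0.005, label: str = ""
) -> Spectrum:
    """One reflectance read for a substrate object of the given type."""
    lam = GRID
    if type == "green_leaf":
        shape = (
            0.04
            + 0.13 * np.exp(-((lam - 555.0) ** 2) / (2.0 * 35.0**2))
            + 0.08 * _logistic((lam - 690.0) / 8.0)  # small NIR rise
        )
    elif type == "leaf_litter":
        # brown: monotone rise concentrated in the far red
        shape = 0.03 + 0.30 * _logistic((lam - 640.0) / 15.0)
    elif type == "trunk":
        shape = 0.035 + 0.10 * _logistic((lam - 640.0) / 15.0)  # low gray-brown
    else:
        raise ValueError(f"unknown substrate type {type!r}")
    vals = shape + rng.normal(0.0, measurement_sd, size=lam.shape)
    return Spectrum(lam.copy(), np.clip(vals, 0.0, 1.0), role="reflectance", label=label)


def generate_study(
    design: StudyDesign = StudyDesign(),
    params: MorphSpectralParams = MorphSpectralParams(),
) -> tuple[SpectrumSet, SpectrumSet, Spectrum]:
    """Fully labeled frog and substrate spectrum sets plus the illuminant.

    Deterministic under ``design.seed``. Defaults yield 288 frog reads
    (9 x 8 x 4) and 162 substrate reads (9 x 3 x 6).
    """
    rng = np.random.default_rng(design.seed)
    frog_spectra, frog_rows = [], []
    for loc, species, morph in design.localities:
        for m in range(1, design.n_males_per_locality + 1):
            indiv = f"{loc}_f{m:02d}"
            offset = rng.normal(0.0, params.individual_sd)
            for r in range(1, design.n_dorsal_reads + 1):
                label = f"{indiv}_r{r}"
                frog_spectra.append(
                    make_frog_spectrum(morph, params, rng, individual_offset=offset, label=label)
                )
                frog_rows.append(
                    {
                        "label": label,
                        "individual": indiv,
                        "species": species,
                        "morph": morph,
                        "locality": loc,
                        "type": None,
                        "replicate": r,
                    }
                )
    frogs = SpectrumSet(frog_spectra, pd.DataFrame(frog_rows))

    sub_spectra, sub_rows = [], []
    for loc, _species, _morph in design.localities:
        for st in design.substrate_types:
            obj = f"{loc}_{st}"
            for r in range(1, design.n_substrate_reads + 1):
                label = f"{obj}_r{r}"
                sub_spectra.append(
                    make_background_spectrum(st, rng, params.measurement_sd, label=label)
                )
                sub_rows.append(
                    {
                        "label": label,
                        "individual": obj,
                        "species": None,
                        "morph": None,
                        "locality": loc,
                        "type": st,
                        "replicate": r,
                    }
                )
    substrates = SpectrumSet(sub_spectra, pd.DataFrame(sub_rows))
    return frogs, substrates, forest_shade_irradiance()


def generate_contrast_table(
    beta: dict[str, float],
    sigma_individual: float,
    sigma_resid: float,
    design: StudyDesign = StudyDesign(),
    seed: int = 0,
    responses: tuple[str, ...] = ("deltaS", "deltaL"),
) -> pd.DataFrame:
    """Balanced LMM-structured records: y = X beta + b_individual + noise.

    ``beta`` maps treatment-coded coefficient names (as produced by
    ``mmi.design_matrix``, e.g. ``morph[red]`` or
    ``morph[red]:predator[crab]``) to values; unnamed coefficients are zero.
    Each response column gets independent noise draws.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for loc, species, morph in design.localities:
        for m in range(1, design.n_males_per_locality + 1):
            indiv = f"{loc}_f{m:02d}"
            for pred in ("bird", "lizard", "crab"):
                for st in design.substrate_types:
                    rows.append(
                        {
                            "individual": indiv,
                            "species": species,
                            "morph": morph,
                            "locality": loc,
                            "predator": pred,
                            "substrate": st,
                        }
                    )
    df = pd.DataFrame(rows)
    full = ModelSpec(
        mains=MAINS,
        interactions=(
            ("species", "morph"),
            ("species", "substrate"),
            ("species", "predator"),
            ("morph", "substrate"),
            ("morph", "predator"),
            ("substrate", "predator"),
        ),
    )
    X, names = design_matrix(full, df)
    unknown = set(beta) - set(names)
    if unknown:
        raise ValueError(f"beta names not in the design: {sorted(unknown)}")
    b = np.array([beta.get(nm, 0.0) for nm in names])
    mu = X @ b
    indiv_codes, ginv = np.unique(df["individual"], return_inverse=True)
    for resp in responses:
        b_ind = rng.normal(0.0, sigma_individual, size=len(indiv_codes))
        eps = rng.normal(0.0, sigma_resid, size=len(df))
        df[resp] = mu + b_ind[ginv] + eps
    return df
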