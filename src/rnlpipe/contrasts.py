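"""Quantum catches and receptor-noise-limited contrasts in JND units.

Chromatic distance (deltaS) uses the receptor-noise-limited model on
log quantum-catch differences; achromatic distance (deltaL) is the Weber-
scaled absolute log ratio of the luminance-channel catches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import GridMismatchError, Spectrum, SpectrumSet
from .visual import VisualSystem


@dataclass
class QuantumCatches:
    """Per-receptor photon catches for one stimulus under one visual system."""

    raw: np.ndarray  # ordered as system.receptor_names
    luminance: float
    label: str
    system: str

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if np.any(self.raw < 0):
            raise ValueError(f"{self.label}: negative quantum catch")

    @property
    def relative(self) -> np.ndarray:
        """Catches normalized to sum 1 (undefined for an all-zero stimulus)."""
        total = self.raw.sum()
        if total <= 0:
            return np.full_like(self.raw, np.nan)
        return self.raw / total

    @property
    def is_dark(self) -> bool:
        return bool(self.raw.sum() <= 0)


def quantum_catch(R: Spectrum, I: Spectrum, system: VisualSystem) -> QuantumCatches:
    """Q_i = sum_lambda R * I * S_i (1-nm grid); luminance catch per the
    system's luminance rule (single dedicated curve, or summed receptor catches).
    """
    S = system.sensitivity_matrix()
    if not (R.on_grid() and I.on_grid()) or S.shape[1] != len(R):
        raise GridMismatchError("R, I and sensitivities must share the 1-nm 300-700 grid")
    prod = R.values * I.values
    raw = S @ prod
    rule = system.luminance_rule
    if rule["mode"] == "single":
        lum = float(system.luminance_sensitivity @ prod)
    else:
        idx = [system.receptor_names.index(n) for n in rule["receptors"]]
        lum = float(raw[idx].sum())
    return QuantumCatches(raw=raw, luminance=lum, label=R.label, system=system.name)


def _check_positive(q: QuantumCatches, system: VisualSystem) -> None:
    bad = np.flatnonzero(q.raw <= 0)
    if len(bad):
        names = [system.receptor_names[i] for i in bad]
        raise ValueError(f"{q.label}: nonpositive quantum catch in receptor(s) {names}")


def delta_S(a: QuantumCatches, b: QuantumCatches, system: VisualSystem) -> float:
    """Receptor-noise-limited chromatic distance in JND (general n).

    With df_i = ln(Q_i,a / Q_i,b) and noise e_i:
        dS^2 = [sum_{i<j} (prod_{k not in {i,j}} e_k^2) (df_i - df_j)^2]
               / [sum_i prod_{k != i} e_k^2]
    which reduces to the familiar dichromat and tetrachromat closed forms.
    """
    if a.system != b.system or a.system != system.name:
        raise ValueError("catch pair and system must match")
    _check_positive(a, system)
    _check_positive(b, system)
    df = np.log(a.raw / b.raw)
    e2 = system.noise() ** 2
    n = len(e2)
    # prod over k != i and k not in {i, j}, via total product ratios
    log_e2 = np.log(e2)
    total = log_e2.sum()
    num = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            num += np.exp(total - log_e2[i] - log_e2[j]) * (df[i] - df[j]) ** 2
    den = np.exp(total - log_e2).sum()
    return float(np.sqrt(num / den))


def delta_L(a: QuantumCatches, b: QuantumCatches, system: VisualSystem) -> float:
    """Achromatic contrast: |ln(Q_L,a / Q_L,b)| / Weber_luminance (JND)."""
    if a.system != b.system or a.system != system.name:
        raise ValueError("catch pair and system must match")
    if a.luminance <= 0 or b.luminance <= 0:
        raise ValueError("nonpositive luminance catch")
    return float(abs(np.log(a.luminance / b.luminance)) / system.weber_luminance)


CONTRAST_COLUMNS = [
    "individual",
    "species",
    "morph",
    "locality",
    "predator",
    "substrate",
    "deltaS",
    "deltaL",
]


def contrast_table(
    frogs: SpectrumSet,
    backgrounds: SpectrumSet,
    I: Spectrum,
    systems: list[VisualSystem],
) -> pd.DataFrame:
    """One row per frog x visual system x substrate type.

    ``frogs`` must be averaged to one spectrum per individual; ``backgrounds``
    to one spectrum per substrate type (design column ``type``).
    """
    if backgrounds.design.empty or "type" not in backgrounds.design:
        raise ValueError("backgrounds need a design table with a 'type' column")
    bg_types = list(backgrounds.design["type"])
    if len(set(bg_types)) != len(bg_types):
        raise ValueError("backgrounds must be averaged to one spectrum per substrate type")
    fd = frogs.design.set_index("label") if not frogs.design.empty else None

    rows = []
    for system in systems:
        bg_catches = {
            t: quantum_catch(backgrounds.get(lab), I, system)
            for t, lab in zip(bg_types, backgrounds.labels())
        }
        for frog in frogs:
            qf = quantum_catch(frog, I, system)
            meta = fd.loc[frog.label] if fd is not None else {}
            for t in bg_types:
                qb = bg_catches[t]
                rows.append(
                    {
                        "individual": meta.get("individual", frog.label),
                        "species": meta.get("species", None),
                        "morph": meta.get("morph", None),
                        "locality": meta.get("locality", None),
                        "predator": system.name,
                        "substrate": t,
                        "deltaS": delta_S(qf, qb, system),
                        "deltaL": delta_L(qf, qb, system),
                    }
                )
    return pd.DataFrame(rows, columns=CONTRAST_COLUMNS)


def flag_outliers(
    records: pd.DataFrame,
    k: float = 3.0,
    cell_keys: tuple[str, ...] = ("locality", "predator", "substrate"),
) -> pd.DataFrame:
    """Flag (never delete) records whose deltaS or deltaL lies more than ``k``
    median-absolute-deviations from its cell median. Exclusion is downstream.
    """
    out = records.reset_index(drop=True).copy()
    flag = np.zeros(len(out), dtype=bool)
    if not np.isinf(k):
        for _, grp in out.groupby(list(cell_keys), dropna=False):
            for col in ("deltaS", "deltaL"):
                v = grp[col].to_numpy(dtype=float)
                med = np.median(v)
                mad = np.median(np.abs(v - med))
                dev = np.abs(v - med)
                flag[grp.index.to_numpy()] |= dev > k * mad
    out["outlier_flag"] = flag
    return out
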