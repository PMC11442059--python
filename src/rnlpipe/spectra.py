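"""Reading, validation, cleaning and aggregation of reflectance/irradiance spectra.

The cleaning pipeline is trim -> clip -> smooth -> interpolate -> average,
applied in that fixed order. Reflectance is stored as a proportion; percent
inputs (max > 2) are auto-detected and divided by 100 with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Common wavelength grid (nm): 300..700 inclusive at 1-nm steps, 401 points.
GRID_LO = 300.0
GRID_HI = 700.0
GRID = np.arange(GRID_LO, GRID_HI + 1.0, 1.0)

DESIGN_COLUMNS = ["label", "individual", "species", "morph", "locality", "type", "replicate"]


class CoverageError(ValueError):
    """A spectrum does not span the requested wavelength range."""


class GridMismatchError(ValueError):
    """Spectra expected on a common wavelength grid are on different grids."""


@dataclass
class Spectrum:
    """A wavelength-indexed curve: reflectance (proportion) or irradiance.

    Wavelengths must be strictly increasing; construction sorts (with a
    warning) if they are not, and rejects duplicated wavelengths.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    role: str = "reflectance"
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.wavelengths_nm.shape != self.values.shape:
            raise ValueError("wavelengths and values must be 1-D arrays of equal length")
        if self.role not in ("reflectance", "irradiance"):
            raise ValueError(f"unknown role {self.role!r}")
        dw = np.diff(self.wavelengths_nm)
        if np.any(dw < 0):
            warnings.warn(
                f"spectrum {self.label!r}: wavelengths not sorted; sorting ascending",
                stacklevel=2,
            )
            order = np.argsort(self.wavelengths_nm, kind="stable")
            self.wavelengths_nm = self.wavelengths_nm[order]
            self.values = self.values[order]
            dw = np.diff(self.wavelengths_nm)
        if np.any(dw == 0):
            raise ValueError(f"spectrum {self.label!r}: duplicated wavelengths")

    def __len__(self) -> int:
        return len(self.wavelengths_nm)

    def copy(self, **changes) -> "Spectrum":
        out = replace(self, **changes)
        out.wavelengths_nm = out.wavelengths_nm.copy()
        out.values = out.values.copy()
        return out

    def on_grid(self, grid: np.ndarray = GRID) -> bool:
        return len(self) == len(grid) and np.array_equal(self.wavelengths_nm, grid)


@dataclass
class SpectrumSet:
    """A collection of spectra plus a per-spectrum metadata (design) table.

    The design table has one row per spectrum label with columns
    (label, individual, species, morph, locality, type, replicate).
    """

    spectra: list[Spectrum] = field(default_factory=list)
    design: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=DESIGN_COLUMNS))

    def __post_init__(self) -> None:
        labels = [s.label for s in self.spectra]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate spectrum labels in set")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def labels(self) -> list[str]:
        return [s.label for s in self.spectra]

    def get(self, label: str) -> Spectrum:
        for s in self.spectra:
            if s.label == label:
                return s
        raise KeyError(label)

    def attach_design(self, design: pd.DataFrame) -> None:
        """Attach a design table; warns about unusual replicate counts."""
        missing = set(self.labels()) - set(design["label"])
        if missing:
            raise ValueError(f"design table missing labels: {sorted(missing)[:5]} ...")
        self.design = design.set_index("label").loc[self.labels()].reset_index()
        self.check_replicates()

    def check_replicates(self) -> None:
        if self.design.empty or "individual" not in self.design:
            return
        d = self.design
        frogs = d[d.get("type").isna()] if "type" in d else d
        if "individual" in frogs and not frogs.empty:
            counts = frogs.groupby("individual").size()
            bad = counts[counts > 4]
            if len(bad):
                warnings.warn(f"{len(bad)} individuals with > 4 dorsal readings", stacklevel=2)
        if "type" in d:
            objs = d[d["type"].notna()]
            if not objs.empty:
                counts = objs.groupby("individual").size()
                bad = counts[counts > 6]
                if len(bad):
                    warnings.warn(f"{len(bad)} substrate objects with > 6 readings", stacklevel=2)

    def map(self, fn) -> "SpectrumSet":
        """Apply ``fn`` to every spectrum, keeping the design table."""
        return SpectrumSet([fn(s) for s in self.spectra], self.design.copy())

    def to_wide_frame(self) -> pd.DataFrame:
        if not self.spectra:
            return pd.DataFrame({"wl": []})
        g0 = self.spectra[0].wavelengths_nm
        for s in self.spectra:
            if not np.array_equal(s.wavelengths_nm, g0):
                raise GridMismatchError("to_wide_frame requires a common grid")
        data = {"wl": g0}
        for s in self.spectra:
            data[s.label] = s.values
        return pd.DataFrame(data)


def _maybe_percent_to_proportion(spec: Spectrum) -> Spectrum:
    if spec.role == "reflectance" and np.nanmax(spec.values) > 2.0:
        warnings.warn(
            f"spectrum {spec.label!r}: max value {np.nanmax(spec.values):.3g} > 2; "
            "interpreting as percent and dividing by 100",
            stacklevel=3,
        )
        spec = spec.copy()
        spec.values = spec.values / 100.0
    return spec


def read_spectra(
    path: str | Path,
    dialect: str = "wide",
    role: str = "reflectance",
    design_path: str | Path | None = None,
) -> SpectrumSet:
    """Read spectra from a CSV file.

    ``wide``: first column is wavelength, one column per spectrum (header =
    label). ``long``: columns (label, wavelength, value). Percent reflectance
    is auto-converted to proportions. A sidecar design CSV may be given.
    """
    path = Path(path)
    if dialect == "wide":
        df = pd.read_csv(path)
        wl_raw = pd.to_numeric(df.iloc[:, 0], errors="coerce")
        if wl_raw.isna().any():
            bad = int(np.flatnonzero(wl_raw.isna().to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric wavelength at data row {bad} "
                f"(value {df.iloc[bad, 0]!r})"
            )
        spectra = []
        for col in df.columns[1:]:
            vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
            spectra.append(Spectrum(wl_raw.to_numpy(), vals, role=role, label=str(col)))
    elif dialect == "long":
        df = pd.read_csv(path)
        if df.shape[1] < 3:
            raise ValueError(f"{path}: long dialect needs columns (label, wavelength, value)")
        df.columns = ["label", "wavelength", "value"] + list(df.columns[3:])
        wl_raw = pd.to_numeric(df["wavelength"], errors="coerce")
        if wl_raw.isna().any():
            bad = int(np.flatnonzero(wl_raw.isna().to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric wavelength at data row {bad} "
                f"(value {df['wavelength'].iloc[bad]!r})"
            )
        df["wavelength"] = wl_raw
        dup = df.duplicated(subset=["label", "wavelength"])
        if dup.any():
            lab = df.loc[dup, "label"].iloc[0]
            raise ValueError(f"{path}: duplicate (label, wavelength) entries, e.g. label {lab!r}")
        spectra = []
        for lab, grp in df.groupby("label", sort=False):
            spectra.append(
                Spectrum(
                    grp["wavelength"].to_numpy(),
                    grp["value"].to_numpy(dtype=float),
                    role=role,
                    label=str(lab),
                )
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    spectra = [_maybe_percent_to_proportion(s) for s in spectra]
    sset = SpectrumSet(spectra)
    if design_path is not None:
        sset.attach_design(pd.read_csv(design_path))
    return sset


def trim_spectrum(s: Spectrum, lo: float = GRID_LO, hi: float = GRID_HI) -> Spectrum:
    """Keep only wavelengths in [lo, hi] (inclusive); error if not covered."""
    if s.wavelengths_nm[0] > lo or s.wavelengths_nm[-1] < hi:
        raise CoverageError(
            f"spectrum {s.label!r} covers [{s.wavelengths_nm[0]:g}, {s.wavelengths_nm[-1]:g}] nm, "
            f"does not span [{lo:g}, {hi:g}] nm"
        )
    keep = (s.wavelengths_nm >= lo) & (s.wavelengths_nm <= hi)
    return Spectrum(s.wavelengths_nm[keep], s.values[keep], role=s.role, label=s.label)


def clip_negatives(s: Spectrum) -> Spectrum:
    """Set negative reflectance values (instrument noise) to zero."""
    if s.role != "reflectance":
        raise ValueError("clip_negatives applies to reflectance spectra only")
    return Spectrum(s.wavelengths_nm.copy(), np.maximum(s.values, 0.0), role=s.role, label=s.label)


def loess_smooth(s: Spectrum, span: float = 0.2) -> Spectrum:
    """Locally weighted quadratic regression (tricube weights), evaluated at
    the input grid; one pass, no robustness iterations. Output clipped at 0.
    """
    x = s.wavelengths_nm
    y = s.values
    n = len(x)
    if n < 10:
        raise ValueError("loess_smooth needs >= 10 points")
    r = int(np.ceil(span * n))
    if r < 4:
        raise ValueError(f"span {span} x n {n} gives window of {r} < 4 points")
    # nearest-r windows: for sorted x these are contiguous slices
    smoothed = np.empty(n)
    # precompute window start indices via two-pointer sweep
    starts = np.empty(n, dtype=int)
    lo = 0
    for i in range(n):
        hi = lo + r
        while hi < n and x[hi] - x[i] < x[i] - x[lo]:
            lo += 1
            hi += 1
        starts[i] = lo
    idx = starts[:, None] + np.arange(r)[None, :]
    xw = x[idx]  # (n, r)
    yw = y[idx]
    d = np.abs(xw - x[:, None])
    dmax = d.max(axis=1, keepdims=True)
    dmax[dmax == 0] = 1.0
    w = (1.0 - (d / dmax) ** 3) ** 3
    w = np.clip(w, 0.0, None)
    # weighted quadratic fit, centered at the target wavelength for conditioning
    t = xw - x[:, None]
    A = np.stack([np.ones_like(t), t, t * t], axis=-1)  # (n, r, 3)
    WA = A * w[..., None]
    ata = np.einsum("nri,nrj->nij", WA, A)
    aty = np.einsum("nri,nr->ni", WA, yw)
    # ridge of machine scale to guard degenerate windows
    ata += 1e-12 * np.eye(3)[None, :, :]
    coef = np.linalg.solve(ata, aty[..., None])[..., 0]
    smoothed = coef[:, 0]  # value at t = 0
    if s.role == "reflectance":
        smoothed = np.maximum(smoothed, 0.0)
    return Spectrum(x.copy(), smoothed, role=s.role, label=s.label)


def interpolate_to_grid(s: Spectrum, step: float = 1.0) -> Spectrum:
    """Linear interpolation onto the 300..700 nm grid; no extrapolation."""
    grid = np.arange(GRID_LO, GRID_HI + step, step)
    if s.wavelengths_nm[0] > grid[0] or s.wavelengths_nm[-1] < grid[-1]:
        raise CoverageError(
            f"spectrum {s.label!r} would require extrapolation onto [{grid[0]:g}, {grid[-1]:g}]"
        )
    vals = np.interp(grid, s.wavelengths_nm, s.values)
    return Spectrum(grid, vals, role=s.role, label=s.label)


def average_replicates(sset: SpectrumSet, by: Sequence[str]) -> SpectrumSet:
    """Pointwise mean spectrum per group of the design table.

    All members of a group must share a wavelength grid. The returned design
    holds the grouping keys plus the group size ``n``.
    """
    if sset.design.empty:
        raise ValueError("average_replicates requires a design table")
    by = list(by)
    design = sset.design
    out_spectra: list[Spectrum] = []
    out_rows = []
    for key, grp in design.groupby(by, sort=True, dropna=False):
        if not isinstance(key, tuple):
            key = (key,)
        members = [sset.get(lab) for lab in grp["label"]]
        g0 = members[0].wavelengths_nm
        for m in members[1:]:
            if not np.array_equal(m.wavelengths_nm, g0):
                raise GridMismatchError(f"group {key}: members on different wavelength grids")
        mean_vals = np.mean([m.values for m in members], axis=0)
        label = "/".join(str(k) for k in key)
        out_spectra.append(Spectrum(g0.copy(), mean_vals, role=members[0].role, label=label))
        row = {"label": label, "n": len(members)}
        row.update(dict(zip(by, key)))
        # carry through metadata constant within the group
        for col in design.columns:
            if col in ("label",) or col in by:
                continue
            uniq = grp[col].dropna().unique()
            if len(uniq) == 1:
                row[col] = uniq[0]
        out_rows.append(row)
    return SpectrumSet(out_spectra, pd.DataFrame(out_rows))


def preprocess(
    sset: SpectrumSet,
    span: float = 0.2,
    lo: float = GRID_LO,
    hi: float = GRID_HI,
    smooth: bool = True,
) -> SpectrumSet:
    """Full cleaning pipeline: trim -> clip -> smooth -> interpolate."""

    def clean(s: Spectrum) -> Spectrum:
        s = trim_spectrum(s, lo, hi)
        if s.role == "reflectance":
            s = clip_negatives(s)
        if smooth:
            s = loess_smooth(s, span=span)
        return interpolate_to_grid(s)

    return sset.map(clean)
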