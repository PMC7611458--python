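"""Parametric metabolite basis set for linear-combination spectral fitting.

The basis is constructed from line lists (chemical shift, proton count,
scalar couplings) rather than density-matrix simulation: each spin group is
expanded into a first-order multiplet and rendered as a sum of
area-normalised Lorentzians on the acquisition's ppm grid.  Unit amplitude
of a rendered basis spectrum corresponds to 1 mmol/L of the metabolite with
all proton counts folded in, so the integral of each rendered spectrum is
proportional to the template's total proton count.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .acquisition import AcquisitionParams

#: Canonical basis roster: the 19 simulated brain metabolites plus the water
#: reference.  Aliases map common alternative labels onto canonical names.
CANONICAL_METABOLITES = frozenset(
    {
        "Ala", "Asp", "Asc", "GPC", "PCho", "Cr", "PCr", "GABA", "Glc",
        "Gln", "Glu", "GSH", "Ins", "Lac", "NAA", "NAAG", "PE", "sIns",
        "Tau", "water",
    }
)

_ALIASES = {
    "PC": "PCho",
    "Cho": "PCho",
    "scyllo-Ins": "sIns",
    "Scyllo": "sIns",
    "scyllo": "sIns",
    "mI": "Ins",
    "myo-Ins": "Ins",
}


def canonical_name(name: str) -> str:
    return _ALIASES.get(name, name)


class InvalidTemplateError(ValueError):
    """A metabolite template violates its invariants."""


@dataclass(frozen=True)
class SpectralLine:
    """A single resonance line: position (ppm), weight, and parent label."""

    ppm: float
    relative_intensity: float
    metabolite: str

    def __post_init__(self) -> None:
        if self.relative_intensity <= 0:
            raise InvalidTemplateError("relative_intensity must be positive")
        if not 0.0 <= self.ppm <= 10.0:
            raise InvalidTemplateError(f"ppm {self.ppm} outside [0, 10]")


@dataclass(frozen=True)
class SpinGroup:
    """One chemically equivalent proton group of a metabolite."""

    ppm: float
    n_protons: int
    j_hz: tuple[float, ...] = ()
    n_partners: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.j_hz) != len(self.n_partners):
            raise InvalidTemplateError("j_hz and n_partners must be parallel lists")


@dataclass(frozen=True)
class MetaboliteTemplate:
    """Line-list description of one metabolite's proton spin groups."""

    name: str
    groups: tuple[SpinGroup, ...]

    def __post_init__(self) -> None:
        cname = canonical_name(self.name)
        if cname not in CANONICAL_METABOLITES:
            raise InvalidTemplateError(
                f"unknown metabolite {self.name!r}; expected one of the "
                f"{len(CANONICAL_METABOLITES)} basis compounds"
            )
        object.__setattr__(self, "name", cname)
        if self.total_protons <= 0:
            raise InvalidTemplateError(f"{self.name}: total proton count must be > 0")

    @property
    def total_protons(self) -> int:
        return sum(g.n_protons for g in self.groups)

    def lines(self, freq_mhz: float) -> list[SpectralLine]:
        """Expand every spin group into its first-order multiplet lines."""
        out: list[SpectralLine] = []
        for g in self.groups:
            out.extend(
                _multi_coupling_lines(
                    g.ppm, g.n_protons, g.j_hz, g.n_partners, freq_mhz, self.name
                )
            )
        return out


def first_order_multiplet(
    shift_ppm: float,
    n_protons: int,
    j_hz: float,
    n_partners: int,
    freq_mhz: float,
    metabolite: str = "",
) -> list[SpectralLine]:
    """First-order multiplet of a proton group coupled to ``n_partners``
    equivalent spin-1/2 partners.

    Returns ``n_partners + 1`` lines centred on ``shift_ppm``, separated by
    ``j_hz / freq_mhz`` ppm, with intensities in binomial (Pascal-triangle)
    ratio summing exactly to ``n_protons``.
    """
    if n_protons <= 0:
        raise InvalidTemplateError("n_protons must be positive")
    if n_partners < 0:
        raise InvalidTemplateError("n_partners must be non-negative")
    if freq_mhz <= 0:
        raise ValueError("freq_mhz must be positive")
    split_ppm = j_hz / freq_mhz
    total_weight = 2**n_partners
    lines = []
    for k in range(n_partners + 1):
        offset = (k - n_partners / 2.0) * split_ppm
        intensity = n_protons * comb(n_partners, k) / total_weight
        lines.append(SpectralLine(shift_ppm + offset, intensity, metabolite))
    return lines


def _multi_coupling_lines(
    shift_ppm: float,
    n_protons: int,
    j_hz: Sequence[float],
    n_partners: Sequence[int],
    freq_mhz: float,
    metabolite: str,
) -> list[SpectralLine]:
    """Sequentially apply first-order splittings for multiple couplings.

    Each (J, partner-count) pair splits every existing line; total intensity
    is preserved exactly at each step.
    """
    if not j_hz:
        return first_order_multiplet(shift_ppm, n_protons, 0.0, 0, freq_mhz, metabolite)
    lines = [SpectralLine(shift_ppm, float(n_protons), metabolite)]
    for j, npart in zip(j_hz, n_partners):
        new: list[SpectralLine] = []
        for ln in lines:
            for sub in first_order_multiplet(
                ln.ppm, n_protons, j, npart, freq_mhz, metabolite
            ):
                new.append(
                    SpectralLine(
                        sub.ppm, sub.relative_intensity * ln.relative_intensity / n_protons,
                        metabolite,
                    )
                )
        lines = new
    return lines


def lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Area-normalised Lorentzian with the given full width at half maximum."""
    hwhm = fwhm / 2.0
    return (hwhm / np.pi) / ((x - center) ** 2 + hwhm**2)


@dataclass
class BasisSet:
    """Rendered metabolite basis on a shared ppm grid.

    ``rendered[name]`` is the real-valued spectrum of 1 mmol/L of the
    metabolite at the base Lorentzian linewidth; amplitudes estimated
    against this basis are therefore in mmol/L-equivalent units.
    """

    templates: dict[str, MetaboliteTemplate]
    rendered: dict[str, np.ndarray]
    acq: AcquisitionParams
    lorentz_fwhm_hz: float
    truncated: dict[str, bool] = field(default_factory=dict)

    @property
    def ppm(self) -> np.ndarray:
        return self.acq.ppm_axis

    @property
    def names(self) -> list[str]:
        return list(self.rendered)

    def metabolite_names(self, include_water: bool = False) -> list[str]:
        return [n for n in self.rendered if include_water or n != "water"]

    def matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Stack rendered spectra as columns, in the given name order."""
        names = list(names) if names is not None else self.names
        return np.column_stack([self.rendered[n] for n in names])

    def to_csv(self, path: str | Path) -> None:
        """Export rendered basis: first column ppm, one column per metabolite."""
        import pandas as pd

        df = pd.DataFrame({"ppm": self.ppm})
        for name, spec in self.rendered.items():
            df[name] = spec
        df.to_csv(path, index=False)


def render_basis(
    templates: Iterable[MetaboliteTemplate],
    acq: AcquisitionParams,
    lorentz_fwhm_hz: float = 2.0,
) -> BasisSet:
    """Render templates as sums of area-normalised Lorentzians on the
    acquisition grid.

    Lines falling outside the grid are truncated with a warning and flagged
    on the returned basis, never silently dropped.
    """
    grid = acq.ppm_axis
    fwhm_ppm = lorentz_fwhm_hz / acq.hz_per_ppm
    rendered: dict[str, np.ndarray] = {}
    tdict: dict[str, MetaboliteTemplate] = {}
    truncated: dict[str, bool] = {}
    for tpl in templates:
        spec = np.zeros_like(grid)
        flag = False
        for line in tpl.lines(acq.spectrometer_freq):
            if not (grid[0] <= line.ppm <= grid[-1]):
                warnings.warn(
                    f"{tpl.name}: line at {line.ppm:.3f} ppm outside grid "
                    f"[{grid[0]:.2f}, {grid[-1]:.2f}]; truncated",
                    stacklevel=2,
                )
                flag = True
                continue
            spec += line.relative_intensity * lorentzian(grid, line.ppm, fwhm_ppm)
        rendered[tpl.name] = spec
        tdict[tpl.name] = tpl
        truncated[tpl.name] = flag
    return BasisSet(
        templates=tdict,
        rendered=rendered,
        acq=acq,
        lorentz_fwhm_hz=lorentz_fwhm_hz,
        truncated=truncated,
    )


def load_basis_library(path: str | Path | None = None) -> list[MetaboliteTemplate]:
    """Load metabolite templates from a JSON line-list library.

    Defaults to the library shipped with the package.  Schema::

        {"metabolites": [{"metabolite": name,
                          "groups": [{"ppm", "n_protons", "j_hz", "n_partners"}]}]}

    where ``j_hz`` / ``n_partners`` may be scalars or parallel lists.
    """
    if path is None:
        with resources.files("mrsquant.data").joinpath("basis_library.json").open() as fh:
            doc = json.load(fh)
    else:
        with open(path) as fh:
            doc = json.load(fh)
    templates = []
    for entry in doc["metabolites"]:
        groups = []
        for g in entry["groups"]:
            j = g.get("j_hz", 0.0)
            npart = g.get("n_partners", 0)
            j = tuple(j) if isinstance(j, (list, tuple)) else ((float(j),) if j else ())
            npart = (
                tuple(npart)
                if isinstance(npart, (list, tuple))
                else ((int(npart),) if npart else ())
            )
            if len(j) != len(npart):
                raise InvalidTemplateError(
                    f"{entry['metabolite']}: j_hz/n_partners length mismatch"
                )
            groups.append(SpinGroup(g["ppm"], g["n_protons"], j, npart))
        templates.append(MetaboliteTemplate(entry["metabolite"], tuple(groups)))
    return templates


def default_basis(
    acq: AcquisitionParams | None = None, lorentz_fwhm_hz: float = 2.0
) -> BasisSet:
    """Render the shipped 20-compound library on the default 7 T grid."""
    if acq is None:
        acq = AcquisitionParams()
    return render_basis(load_basis_library(), acq, lorentz_fwhm_hz)
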