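"""Tissue optical properties for the five-layer head model.

The bundled table carries, per tissue and wavelength, the absorption
coefficient ``mu_a``, the reduced scattering coefficient ``mu_s'``, the
Henyey-Greenstein anisotropy factor ``g`` and the refractive index ``n``.
All coefficients are stored in mm^-1 (literature tables quoted in cm^-1 are
divided by 10 on ingest, since the head grids are 1 mm voxels).

Bundled wavelengths are the three NIRS bands 690/780/830 nm plus the 800 nm
set used for the single-wavelength studies.  At 690/780/830 nm white matter
deliberately duplicates gray matter, as published.  Refractive indices are
not part of the published table; the standard soft-tissue default n = 1.4
(air 1.0) is applied and can be overridden per tissue.

Whether a scattering value feeds the transport kernel as the reduced
coefficient or is first un-reduced via the similarity relation
``mu_s = mu_s' / (1 - g)`` is the engine's choice (see
``nirsim.mc.SimulationConfig.scattering_mode``); this module only stores
``mu_s'`` as printed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import AIR, CSF, GRAY, N_CODES, SCALP, SKULL, TISSUE_CODES, TISSUE_NAMES, WHITE

#: Wavelengths (nm) for which bundled optical properties exist.
SUPPORTED_WAVELENGTHS = (690, 780, 800, 830)

#: Default anisotropy factor, identical for all five tissues.
DEFAULT_G = 0.92

#: Default refractive indices (air 1.0, soft tissue 1.4).
DEFAULT_N_TISSUE = 1.4
DEFAULT_N_AIR = 1.0


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one tissue at one wavelength (mm^-1 units)."""

    mu_a: float          # absorption coefficient, mm^-1
    mu_s_reduced: float  # reduced scattering coefficient mu_s', mm^-1
    g_hg: float          # Henyey-Greenstein anisotropy factor
    n_refr: float        # refractive index

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s_reduced < 0:
            raise ValueError("mu_a and mu_s_reduced must be >= 0")
        if not -1.0 < self.g_hg < 1.0:
            raise ValueError(f"anisotropy g must lie in (-1, 1), got {self.g_hg}")
        if self.n_refr < 1.0:
            raise ValueError(f"refractive index must be >= 1, got {self.n_refr}")


def mus_from_reduced(mu_s_reduced: float, g_hg: float) -> float:
    """Un-reduce a scattering coefficient: ``mu_s = mu_s' / (1 - g)``.

    The similarity relation recovers the true scattering rate paired with an
    anisotropic phase function from the isotropic-equivalent ``mu_s'``.
    """
    if not 0.0 <= g_hg < 1.0:
        raise ValueError(f"g must satisfy 0 <= g < 1 for un-reduction, got {g_hg}")
    if mu_s_reduced < 0:
        raise ValueError("mu_s_reduced must be >= 0")
    return mu_s_reduced / (1.0 - g_hg)


# Published per-tissue (mu_a, mu_s') pairs, cm^-1, at the three NIRS bands.
_NIRS_BANDS_CM = {
    #            690 nm          780 nm          830 nm
    SCALP: ((0.159, 8.0), (0.164, 7.1), (0.191, 6.6)),
    SKULL: ((0.101, 10.0), (0.115, 9.1), (0.136, 8.6)),
    CSF: ((0.004, 0.1), (0.017, 0.1), (0.026, 0.1)),
    GRAY: ((0.178, 12.5), (0.170, 11.6), (0.186, 11.1)),
    WHITE: ((0.178, 12.5), (0.170, 11.6), (0.186, 11.1)),  # duplicates GM as published
}
_NIRS_BAND_ORDER = (690, 780, 830)

# 800 nm list, already mm^-1, quoted as scattering/absorption; stored as
# (mu_a, mu_s') following the same reduced-scattering convention as the table.
_EIGHT_HUNDRED_MM = {
    SCALP: (0.018, 1.9),
    SKULL: (0.016, 1.6),
    CSF: (0.004, 0.24),
    GRAY: (0.036, 2.2),
    WHITE: (0.014, 9.1),
}


class TissueOpticalTable:
    """Mapping ``(tissue code, wavelength nm) -> OpticalProperties``.

    Every tissue code 1..5 has an entry at every wavelength of the table.
    Air (code 0) maps to a non-interacting medium with ``n = n_air``.
    """

    def __init__(self, entries: dict[tuple[int, int], OpticalProperties],
                 n_air: float = DEFAULT_N_AIR):
        self._entries = dict(entries)
        self.n_air = float(n_air)
        self.wavelengths = tuple(sorted({wl for _, wl in self._entries}))
        for wl in self.wavelengths:
            for code in range(1, N_CODES):
                if (code, wl) not in self._entries:
                    raise ValueError(
                        f"incomplete table: tissue {TISSUE_NAMES[code]} missing at {wl} nm"
                    )

    def get(self, tissue: int | str, wavelength_nm: int) -> OpticalProperties:
        code = TISSUE_CODES[tissue] if isinstance(tissue, str) else int(tissue)
        if code == AIR:
            return OpticalProperties(0.0, 0.0, 0.0, self.n_air)
        key = (code, int(wavelength_nm))
        if key not in self._entries:
            raise KeyError(
                f"no optical properties for tissue {TISSUE_NAMES.get(code, code)} at "
                f"{wavelength_nm} nm; available wavelengths: {self.wavelengths}"
            )
        return self._entries[key]

    def with_refractive_index(self, n_by_tissue: dict[int, float]) -> "TissueOpticalTable":
        """Return a copy with per-tissue refractive indices overridden."""
        entries = {
            (code, wl): (replace(props, n_refr=n_by_tissue[code])
                         if code in n_by_tissue else props)
            for (code, wl), props in self._entries.items()
        }
        return TissueOpticalTable(entries, n_air=self.n_air)

    # -- kernel-facing arrays -------------------------------------------------

    def coefficient_arrays(self, wavelength_nm: int, scattering_mode: str = "as-paper"):
        """Per-code coefficient arrays ``(mu_a, mu_s, g, n)`` for the transport kernel.

        ``scattering_mode``:

        * ``"as-paper"`` — the tabulated mu_s' is used directly as the
          scattering rate while the phase function keeps its anisotropy g.
        * ``"physical"`` — the rate is un-reduced, ``mu_s = mu_s'/(1-g)``.

        Index 0 (air) is non-scattering, non-absorbing, ``n = n_air``.
        """
        if scattering_mode not in ("as-paper", "physical"):
            raise ValueError(f"unknown scattering mode {scattering_mode!r}")
        mu_a = np.zeros(N_CODES)
        mu_s = np.zeros(N_CODES)
        g = np.zeros(N_CODES)
        n = np.full(N_CODES, self.n_air)
        for code in range(1, N_CODES):
            props = self.get(code, wavelength_nm)
            mu_a[code] = props.mu_a
            g[code] = props.g_hg
            n[code] = props.n_refr
            if scattering_mode == "physical":
                mu_s[code] = mus_from_reduced(props.mu_s_reduced, props.g_hg)
            else:
                mu_s[code] = props.mu_s_reduced
        return mu_a, mu_s, g, n

    # -- text round trip ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tissue": TISSUE_NAMES[code],
                "wavelength_nm": wl,
                "mu_a_mm": props.mu_a,
                "mu_s_reduced_mm": props.mu_s_reduced,
                "g": props.g_hg,
                "n": props.n_refr,
            }
            for (code, wl), props in sorted(self._entries.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path | io.IOBase) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path | io.IOBase, n_air: float = DEFAULT_N_AIR
                 ) -> "TissueOpticalTable":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        required = {"tissue", "wavelength_nm", "mu_a_mm", "mu_s_reduced_mm", "g", "n"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"tissue table file lacks columns {sorted(missing)}")
        entries = {
            (TISSUE_CODES[row.tissue], int(row.wavelength_nm)): OpticalProperties(
                row.mu_a_mm, row.mu_s_reduced_mm, row.g, row.n
            )
            for row in df.itertuples()
        }
        return cls(entries, n_air=n_air)


def build_tissue_table(
    wavelengths: set[int] | tuple[int, ...] = SUPPORTED_WAVELENGTHS,
    g_hg: float = DEFAULT_G,
    n_tissue: float = DEFAULT_N_TISSUE,
    n_air: float = DEFAULT_N_AIR,
) -> TissueOpticalTable:
    """Build the bundled five-tissue optical table at the requested wavelengths.

    Values at 690/780/830 nm come from the published cm^-1 table (divided by
    10); the 800 nm values are the published mm^-1 list.  Requesting any other
    wavelength raises, naming the supported set.
    """
    wavelengths = tuple(sorted(int(w) for w in set(wavelengths)))
    bad = [w for w in wavelengths if w not in SUPPORTED_WAVELENGTHS]
    if bad:
        raise ValueError(
            f"unsupported wavelength(s) {bad}; bundled properties exist for "
            f"{sorted(SUPPORTED_WAVELENGTHS)} nm"
        )
    entries: dict[tuple[int, int], OpticalProperties] = {}
    for wl in wavelengths:
        for code in (SCALP, SKULL, CSF, GRAY, WHITE):
            if wl == 800:
                mu_a, mu_sp = _EIGHT_HUNDRED_MM[code]
            else:
                mu_a_cm, mu_sp_cm = _NIRS_BANDS_CM[code][_NIRS_BAND_ORDER.index(wl)]
                mu_a, mu_sp = mu_a_cm / 10.0, mu_sp_cm / 10.0
            entries[(code, wl)] = OpticalProperties(mu_a, mu_sp, g_hg, n_tissue)
    return TissueOpticalTable(entries, n_air=n_air)
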