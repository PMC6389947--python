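"""Plain-text I/O for traces and spectra.

Two-column CSV/TSV files (header optional) carry all measured data;
per-trace metadata (addition time, ionophore maximum, membrane
condition) lives in a JSON sidecar or is passed explicitly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cd import CDSpectrum
from .ftir import PolarizedSpectrumPair
from .kinetics import FluorescenceTrace

__all__ = [
    "read_xy",
    "read_trace",
    "write_trace",
    "read_spectrum_pair",
    "read_cd_spectrum",
    "write_xy",
]


def read_xy(path: str | Path, sep: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column numeric file; a single header line is detected
    and skipped automatically.  The separator is sniffed (comma, tab or
    whitespace) unless given."""
    path = Path(path)
    kwargs = {"sep": sep} if sep is not None else {"sep": None, "engine": "python"}
    df = pd.read_csv(path, header=None, comment="#", **kwargs)
    first = df.iloc[0]
    try:
        first.astype(float)
    except (ValueError, TypeError):
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns, got {df.shape[1]}")
    data = df.iloc[:, :2].astype(float).to_numpy()
    return data[:, 0], data[:, 1]


def write_xy(
    path: str | Path, x: np.ndarray, y: np.ndarray, header: tuple[str, str]
) -> None:
    pd.DataFrame({header[0]: x, header[1]: y}).to_csv(path, index=False)


def read_trace(
    path: str | Path,
    t_add: float | None = None,
    f_max: float | None = None,
    sidecar: str | Path | None = None,
) -> FluorescenceTrace:
    """Read a fluorescence trace from a (time_s, intensity) file.

    ``t_add``/``f_max`` may come from arguments or from a JSON sidecar
    (same stem with ``.json``, or an explicit path) with keys ``t_add``
    and ``f_max``; explicit arguments win.
    """
    path = Path(path)
    meta: dict = {}
    sidecar_path = Path(sidecar) if sidecar else path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    if t_add is None:
        t_add = meta.get("t_add")
    if f_max is None:
        f_max = meta.get("f_max")
    if t_add is None:
        raise ValueError(
            f"{path}: no addition time; pass t_add or provide it in {sidecar_path.name}"
        )
    time, intensity = read_xy(path)
    return FluorescenceTrace(
        time=time, intensity=intensity, t_add=float(t_add),
        f_max=None if f_max is None else float(f_max),
        meta={k: v for k, v in meta.items() if k not in ("t_add", "f_max")},
    )


def write_trace(path: str | Path, trace: FluorescenceTrace) -> None:
    write_xy(path, trace.time, trace.intensity, ("time_s", "intensity"))
    sidecar = {"t_add": trace.t_add}
    if trace.f_max is not None:
        sidecar["f_max"] = trace.f_max
    Path(path).with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_spectrum_pair(
    par_path: str | Path, perp_path: str | Path
) -> PolarizedSpectrumPair:
    """Read matched parallel/perpendicular absorbance spectra from two
    (wavenumber_cm-1, absorbance) files sharing one grid."""
    nu_par, a_par = read_xy(par_path)
    nu_perp, a_perp = read_xy(perp_path)
    if nu_par.shape != nu_perp.shape or not np.allclose(nu_par, nu_perp):
        raise ValueError(
            f"{par_path} and {perp_path} are not on the same wavenumber grid"
        )
    return PolarizedSpectrumPair(
        wavenumber=nu_par, absorbance_par=a_par, absorbance_perp=a_perp
    )


def read_cd_spectrum(path: str | Path, units: str = "a.u.") -> CDSpectrum:
    """Read a CD spectrum from a (wavelength_nm, ellipticity) file."""
    wl, el = read_xy(path)
    return CDSpectrum(wavelength=wl, ellipticity=el, units=units)
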