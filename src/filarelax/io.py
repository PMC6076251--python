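"""Config and delimited-table I/O.

Configs are YAML (or JSON, a YAML subset) mappings with keys
``E_Pa``, ``G_Pa`` (or ``poisson_ratio``), ``r_um``, ``kappa``, ``eta``,
``eta_b``, ``eta_s``.  Internally everything is SI; the micrometre
radius key is the one deliberate convenience.  Tables are 2-column
delimited text with '#' comments: (lag_s, acf) for autocorrelations and
(length_um, tau_s) for length-scaling datasets.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .fit import ACFSeries
from .properties import FilamentProperties, InvalidParameterError
from .scaling import LengthScalingDataset


def load_config(path) -> FilamentProperties:
    """Read filament properties from a YAML/JSON config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidParameterError(f"config {path} is not a mapping")
    return properties_from_dict(cfg)


def properties_from_dict(cfg: dict) -> FilamentProperties:
    """Build :class:`FilamentProperties` from config keys."""
    try:
        E = float(cfg["E_Pa"])
        r = float(cfg["r_um"]) * 1e-6
    except KeyError as e:
        raise InvalidParameterError(f"config missing required key {e}") from e
    kwargs = dict(
        kappa=float(cfg.get("kappa", 0.75)),
        eta=float(cfg.get("eta", 0.0)),
        eta_b=float(cfg.get("eta_b", 0.0)),
        eta_s=float(cfg.get("eta_s", 0.0)),
    )
    if "G_Pa" in cfg:
        return FilamentProperties(E=E, G=float(cfg["G_Pa"]), r=r, **kwargs)
    if "poisson_ratio" in cfg:
        return FilamentProperties.from_poisson(
            E=E, poisson_ratio=float(cfg["poisson_ratio"]), r=r, **kwargs
        )
    raise InvalidParameterError("config needs either G_Pa or poisson_ratio")


def _read_two_columns(path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, comments="#", delimiter=None if _is_ws(path) else ",")
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise InvalidParameterError(f"{path}: expected two columns")
    return data[:, 0], data[:, 1]


def _is_ws(path) -> bool:
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            return "," not in s
    return True


def read_acf(path) -> ACFSeries:
    """Read an autocorrelation series from (lag_s, acf) delimited text."""
    lags, values = _read_two_columns(path)
    return ACFSeries(lags=lags, values=values)


def write_acf(path, series: ACFSeries) -> None:
    """Write an autocorrelation series as (lag_s, acf) CSV."""
    np.savetxt(
        path,
        np.column_stack([series.lags, series.values]),
        delimiter=",",
        header="lag_s,acf",
    )


def read_scaling(path) -> LengthScalingDataset:
    """Read a length-scaling dataset from (length_um, tau_s) text."""
    L_um, tau = _read_two_columns(path)
    return LengthScalingDataset(lengths=L_um * 1e-6, taus=tau)


def write_scaling(path, data: LengthScalingDataset) -> None:
    """Write a length-scaling dataset as (length_um, tau_s) CSV."""
    np.savetxt(
        path,
        np.column_stack([data.lengths * 1e6, data.taus]),
        delimiter=",",
        header="length_um,tau_s",
    )
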