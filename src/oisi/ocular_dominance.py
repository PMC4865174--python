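"""Ocular dominance from per-eye response integrals.

For each SF threshold t, the response integral of each eye is the
trapezoidal integral of its (un-normalized) tuning magnitudes over
log10(SF) restricted to SF >= t, and the ocular dominance index is the
contrast formula

    ODI(t) = (C(t) − I(t)) / (C(t) + I(t))

bounded in [-1, 1]; +1 means a purely contralateral response, −1 purely
ipsilateral.  Integrating the tail above each threshold lets the profile
express dominance shifts confined to high spatial frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .tuning import TuningCurve

__all__ = ["ODProfile", "response_integral", "odi", "odi_profile", "save_od_profile"]


@dataclass
class ODProfile:
    """Ocular dominance index per SF threshold, with the per-eye integrals."""

    thresholds_cpd: np.ndarray
    odi: np.ndarray              # NaN where both integrals vanish
    contra_integral: np.ndarray
    ipsi_integral: np.ndarray

    def __post_init__(self) -> None:
        defined = np.isfinite(self.odi)
        if np.any(np.abs(self.odi[defined]) > 1 + 1e-12):
            raise ValueError("odi out of [-1, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_cpd": self.thresholds_cpd,
                "contra_integral": self.contra_integral,
                "ipsi_integral": self.ipsi_integral,
                "odi": self.odi,
            }
        )


def response_integral(curve: TuningCurve, threshold_cpd: float, domain: str = "log10") -> float:
    """Trapezoidal integral of the tuning magnitudes over SF >= threshold.

    ``domain`` selects the integration variable: "log10" (log10 cpd,
    matching the log-spaced design) or "linear" (cpd).  Returns 0 when a
    single point remains at the threshold.
    """
    sf = curve.sf_values_cpd
    if threshold_cpd > sf[-1] * (1 + 1e-9):
        raise ValueError(f"threshold {threshold_cpd} above the highest tested SF {sf[-1]}")
    if threshold_cpd < sf[0] * (1 - 1e-9):
        raise ValueError(f"threshold {threshold_cpd} below the lowest tested SF {sf[0]}")
    sel = sf >= threshold_cpd * (1 - 1e-9)
    if sel.sum() < 2:
        return 0.0
    x = np.log10(sf[sel]) if domain == "log10" else sf[sel]
    if domain not in ("log10", "linear"):
        raise ValueError(f"unknown integration domain {domain!r}")
    return float(np.trapezoid(curve.magnitudes[sel], x))


def odi(contra_integral: float, ipsi_integral: float) -> float:
    """Contrast-formula ocular dominance index, in [-1, 1]."""
    if contra_integral < 0 or ipsi_integral < 0:
        raise ValueError("response integrals must be >= 0")
    total = contra_integral + ipsi_integral
    if total <= 0:
        raise ValueError("both response integrals are zero: ODI undefined")
    return (contra_integral - ipsi_integral) / total


def odi_profile(contra: TuningCurve, ipsi: TuningCurve, domain: str = "log10") -> ODProfile:
    """ODI at every tested SF threshold, from un-normalized per-eye curves."""
    if contra.normalized or ipsi.normalized:
        raise ValueError("odi_profile requires un-normalized curves (absolute comparability)")
    if contra.sf_values_cpd.shape != ipsi.sf_values_cpd.shape or not np.allclose(
        contra.sf_values_cpd, ipsi.sf_values_cpd
    ):
        raise ValueError("curves are on different SF grids")
    thresholds = contra.sf_values_cpd.copy()
    c_int = np.array([response_integral(contra, t, domain) for t in thresholds])
    i_int = np.array([response_integral(ipsi, t, domain) for t in thresholds])
    vals = np.full(len(thresholds), np.nan)
    defined = (c_int + i_int) > 0
    vals[defined] = (c_int[defined] - i_int[defined]) / (c_int[defined] + i_int[defined])
    return ODProfile(thresholds_cpd=thresholds, odi=vals, contra_integral=c_int, ipsi_integral=i_int)


def save_od_profile(profile: ODProfile, csv_path: str | Path, json_path: Optional[str | Path] = None) -> None:
    df = profile.to_dataframe()
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        defined = np.isfinite(profile.odi)
        summary = {
            "n_thresholds": int(len(profile.thresholds_cpd)),
            "n_defined": int(defined.sum()),
            "odi_at_lowest_threshold": float(profile.odi[0]) if defined[0] else None,
        }
        Path(json_path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
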