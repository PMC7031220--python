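"""Age-depth dating utilities and site-metadata arithmetic.

Horizon deposition dates come from radiometric anchors (e.g. 210Pb/137Cs
constant-rate-of-supply chronologies or varve counts): depths inside the
anchored range are dated by linear interpolation between bracketing
anchors; deeper depths by extrapolating a second-order polynomial fitted
to all anchors.  Extrapolated dates earlier than 1750 CE are excluded,
since chronologies below supported 210Pb become unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AgeDepthModel", "SiteRecord", "date_horizons", "catchment_ratio", "SITE_TABLE"]

DATE_FLOOR = 1750.0


@dataclass(frozen=True)
class AgeDepthModel:
    """Quadratic age-depth model fitted to (depth cm, date CE) anchors."""

    depths: np.ndarray
    dates: np.ndarray
    coeffs: np.ndarray  # quadratic date(depth) coefficients, highest first
    r_squared: float
    date_floor: float = DATE_FLOOR

    @classmethod
    def fit(cls, anchors) -> "AgeDepthModel":
        depths = np.asarray([a[0] for a in anchors], dtype=float)
        dates = np.asarray([a[1] for a in anchors], dtype=float)
        if len(depths) < 2:
            raise ValueError("need at least 2 dated anchors")
        if np.any(np.diff(depths) <= 0):
            raise ValueError("anchor depths must strictly increase")
        if np.any(np.diff(dates) >= 0):
            raise ValueError("anchor dates must strictly decrease with depth")
        deg = 2 if len(depths) >= 3 else 1
        coeffs = np.polyfit(depths, dates, deg)
        fitted = np.polyval(coeffs, depths)
        sst = float(np.sum((dates - dates.mean()) ** 2))
        r2 = 1.0 - float(np.sum((dates - fitted) ** 2)) / sst if sst > 0 else 1.0
        return cls(depths=depths, dates=dates, coeffs=coeffs, r_squared=r2)


def date_horizons(anchors, depths) -> pd.DataFrame:
    """Date sediment depths from radiometric anchors.

    Returns a DataFrame with columns ``depth_cm``, ``date_CE``, ``method``
    (interpolated / extrapolated), and ``included`` with an exclusion
    ``reason`` for dates before the 1750 CE floor.
    """
    model = AgeDepthModel.fit(anchors)
    q = np.asarray(depths, dtype=float)
    rows = []
    for d in q:
        if d < model.depths[0]:
            raise ValueError(
                f"depth {d} above the shallowest anchor ({model.depths[0]} cm)"
            )
        if d <= model.depths[-1]:
            date = float(np.interp(d, model.depths, model.dates))
            method = "interpolated"
        else:
            date = float(np.polyval(model.coeffs, d))
            method = "extrapolated"
        ok = date >= model.date_floor
        rows.append(
            {
                "depth_cm": float(d),
                "date_CE": date,
                "method": method,
                "included": ok,
                "reason": "" if ok else f"date {date:.1f} precedes the {model.date_floor:.0f} CE floor",
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SiteRecord:
    """Geomorphological description of one sampling site."""

    site_id: str
    name: str = ""
    lake_area_km2: float | None = None
    watershed_area_km2: float | None = None
    latitude: float | None = None
    longitude: float | None = None
    peak_thg_ng_g: float | None = None


def catchment_ratio(record: SiteRecord) -> float | None:
    """Watershed-to-lake area ratio, to 3 significant figures.

    Returns None where an area is unavailable (rivers have no defined
    lake area).
    """
    if not record.lake_area_km2 or not record.watershed_area_km2:
        return None
    if record.lake_area_km2 <= 0 or record.watershed_area_km2 <= 0:
        raise ValueError("areas must be positive")
    ratio = record.watershed_area_km2 / record.lake_area_km2
    return float(np.format_float_positional(ratio, precision=3, fractional=False, unique=False))


# Published geomorphological characterisation of the nine study sites
# (lake and watershed areas in km^2, peak total mercury in ng/g dw).
SITE_TABLE: tuple[SiteRecord, ...] = (
    SiteRecord("HAR", "Kokemaenjoki/Harjavalta", None, 26100.0, 61.33207, 22.12895, 2739.0),
    SiteRecord("POK", "Pocket Lake", 0.048, 0.095, 62.50897, -114.37377, 1906.0),
    SiteRecord("OJA", "Ojanjarvi", 12.0, 3970.0, 63.80657, 22.99994, 1057.0),
    SiteRecord("PAI", "Paivajarvi", 0.13, 0.95, 63.88923, 23.24727, 415.0),
    SiteRecord("AQT", "Aquatuk Lake", 8.28, 231.0, 54.3281, -84.5686, 110.0),
    SiteRecord("PUL", "Pulmankijarvi", 11.2, 800.0, 69.97459, 28.00415, 126.0),
    SiteRecord("KEV", "Kevojarvi", 1.1, 1470.0, 69.75804, 26.99785, 91.0),
    SiteRecord("LAH", "Lake Hazen", 540.0, 6860.0, 81.8245, -70.71604, 63.0),
    SiteRecord("VUO", "Vuolimus Cieskuljavri", 0.39, 22.5, 69.73197, 27.09612, 50.0),
)
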