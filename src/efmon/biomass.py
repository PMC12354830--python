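"""WBF-to-body-mass lookup over a region-structured reference table.

The reference table maps wing-beat frequencies to body masses for insect
taxa, partitioned into a dense region (<= 240 Hz, many candidates per
frequency), a less dense region (240-340 Hz), and a sparse region
(> 340 Hz, mostly mosquitoes). Mass estimation expands a +-0.5 Hz search
window around the event's mean WBF until candidates appear or the window
cap max(10, sigma)/2 is reached, then resolves ambiguity with the Europe
presence flag and observation-probability weighting; region-specific
fallbacks cover the no-candidate case.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ContractError, FormatError

REQUIRED_COLUMNS = ("taxon", "wbf_hz", "mass_mg", "in_europe", "obs_prob")
DENSE_MAX_HZ = 240.0
LESS_DENSE_MAX_HZ = 340.0
SPARSE_FALLBACK_HZ = 480.0
WINDOW_STEP_HZ = 0.5
EXACT_TOL_HZ = 0.01


@dataclass
class BiomassEstimate:
    mass_mg: float
    region: str
    method: str  # exact | window | fallback_median | fallback_480 | weighted | zero
    n_candidates_initial: int
    n_candidates_after_europe: int
    halfwidth_hz: float = 0.0
    event_id: str = ""


def region_of(wbf_hz: float) -> str:
    """dense (<= 240 Hz), less_dense ((240, 340] Hz), sparse (> 340 Hz)."""
    if wbf_hz <= 0:
        raise ContractError("wbf must be positive")
    if wbf_hz <= DENSE_MAX_HZ:
        return "dense"
    if wbf_hz <= LESS_DENSE_MAX_HZ:
        return "less_dense"
    return "sparse"


class ReferenceTable:
    """Validated WBF -> body-mass entries with cached fallbacks."""

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)
        self.df["region"] = [region_of(v) for v in self.df["wbf_hz"]]
        self._median = {
            r: float(sub["mass_mg"].median())
            for r, sub in self.df.groupby("region")
        }
        sparse_idx = (self.df["wbf_hz"] - SPARSE_FALLBACK_HZ).abs().idxmin()
        self._mass_near_480 = float(self.df.loc[sparse_idx, "mass_mg"])
        self._wbf_near_480 = float(self.df.loc[sparse_idx, "wbf_hz"])

    def __len__(self) -> int:
        return len(self.df)

    def region_counts(self) -> dict[str, int]:
        counts = self.df["region"].value_counts().to_dict()
        return {r: int(counts.get(r, 0)) for r in ("dense", "less_dense", "sparse")}

    def region_median(self, region: str) -> float:
        """Median mass of a region; empty regions degrade to the dense
        median, then to the whole-table median."""
        if region in self._median:
            return self._median[region]
        if "dense" in self._median:
            return self._median["dense"]
        if len(self.df):
            return float(self.df["mass_mg"].median())
        raise ConfigError("empty reference table")

    def mass_at_480(self) -> float:
        # nearest-480 Hz entry stands in for "the body mass of a mosquito"
        if abs(self._wbf_near_480 - SPARSE_FALLBACK_HZ) > 100:
            raise ConfigError(
                "reference table lacks an entry near 480 Hz for the sparse fallback"
            )
        return self._mass_near_480


def load_reference_table(path: str | Path) -> ReferenceTable:
    """Load and validate the CSV reference table.

    Expected columns: taxon, wbf_hz, mass_mg, in_europe, obs_prob. Row
    numbers in error messages are 1-based data rows (excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"reference table missing columns: {missing}")
    for i, row in df.iterrows():
        if not row["wbf_hz"] > 0:
            raise FormatError(f"row {i + 1}: wbf_hz must be positive")
        if not row["mass_mg"] > 0:
            raise FormatError(f"row {i + 1}: mass_mg must be positive")
        if not 0 <= row["obs_prob"] <= 1:
            raise FormatError(f"row {i + 1}: obs_prob must be in [0, 1]")
    df["in_europe"] = df["in_europe"].astype(bool)
    return ReferenceTable(df)


def find_candidates(
    mu_f0: float, sigma_f0: float, table: ReferenceTable
) -> tuple[pd.DataFrame, float]:
    """Expanding-window candidate search around ``mu_f0``.

    Exact matches (|mu - wbf| < 0.01 Hz) win at half-width 0; otherwise the
    window grows in 0.5 Hz steps while the half-width stays within
    max(10, sigma_f0) / 2. Returns (candidates, half-width used).
    """
    wbf = table.df["wbf_hz"].to_numpy()
    exact = np.abs(wbf - mu_f0) < EXACT_TOL_HZ
    if exact.any():
        return table.df[exact], 0.0
    cap = max(10.0, sigma_f0) / 2.0
    halfwidth = WINDOW_STEP_HZ
    while halfwidth <= cap:
        hit = np.abs(wbf - mu_f0) <= halfwidth
        if hit.any():
            return table.df[hit], halfwidth
        halfwidth += WINDOW_STEP_HZ
    return table.df.iloc[0:0], min(halfwidth - WINDOW_STEP_HZ, cap)


def estimate_mass(
    mu_f0: float,
    sigma_f0: float,
    table: ReferenceTable,
    fallback_dense_median: bool = False,
    event_id: str = "",
) -> BiomassEstimate:
    """Resolve one event's body mass through the lookup decision tree.

    No candidates: dense and less-dense regions fall back to a median mass
    (each region's own median by default; ``fallback_dense_median`` makes
    the less-dense region reuse the dense median) and the sparse region
    falls back to the mass of the entry nearest 480 Hz. One candidate: its
    mass. Several: filter by Europe presence, then 0 -> mass 0, 1 -> its
    mass, >1 -> observation-probability-weighted average.
    """
    region = region_of(mu_f0)
    cands, halfwidth = find_candidates(mu_f0, sigma_f0, table)
    n0 = len(cands)
    if n0 == 0:
        if region == "sparse":
            return BiomassEstimate(
                table.mass_at_480(), region, "fallback_480", 0, 0, halfwidth, event_id
            )
        median_region = "dense" if (region == "dense" or fallback_dense_median) else region
        return BiomassEstimate(
            table.region_median(median_region),
            region,
            "fallback_median",
            0,
            0,
            halfwidth,
            event_id,
        )
    if n0 == 1:
        method = "exact" if halfwidth == 0.0 else "window"
        return BiomassEstimate(
            float(cands["mass_mg"].iloc[0]), region, method, 1, 1, halfwidth, event_id
        )
    eu = cands[cands["in_europe"]]
    n1 = len(eu)
    if n1 == 0:
        return BiomassEstimate(0.0, region, "zero", n0, 0, halfwidth, event_id)
    if n1 == 1:
        method = "exact" if halfwidth == 0.0 else "window"
        return BiomassEstimate(
            float(eu["mass_mg"].iloc[0]), region, method, n0, 1, halfwidth, event_id
        )
    weights = eu["obs_prob"].to_numpy(dtype=float)
    masses = eu["mass_mg"].to_numpy(dtype=float)
    mass = float((masses * weights).sum() / weights.sum())
    return BiomassEstimate(mass, region, "weighted", n0, n1, halfwidth, event_id)


def wbf_mass_correlation(table: ReferenceTable) -> tuple[float, float]:
    """Pearson correlation of WBF against body mass over all entries."""
    if len(table) < 3:
        raise ContractError("need at least 3 entries")
    wbf = table.df["wbf_hz"].to_numpy(dtype=float)
    mass = table.df["mass_mg"].to_numpy(dtype=float)
    if np.ptp(wbf) == 0 or np.ptp(mass) == 0:
        raise ContractError("correlation undefined for a constant column")
    r, p = stats.pearsonr(wbf, mass)
    return float(r), float(p)
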