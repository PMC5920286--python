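"""Post-simulation probabilistic dementia allocation.

Dementia status is not modelled by the engine's transition machinery; it is
assigned after the run, conditional on age group, MMSE band and
community/care-home residence, via an allocation table of cell
probabilities.  The default mode draws one persistent uniform quantile
``u ~ U(0,1)`` per individual per run and sets ``dementia = (u < p_cell)``
in every snapshot: with a table that rises with age and falls with MMSE,
an individual's cell probability is non-decreasing along their trajectory,
so onset is effectively monotone while the expected prevalence in each cell
equals the cell probability.  An independent-per-snapshot mode is also
provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import SimulationOutput
from .errors import TableCoverageError, ConfigurationError
from .state import MMSE_BAND_LEVELS, RESIDENCE_LEVELS, mmse_band_from_score

AGE_GROUP_EDGES = (35, 65, 75, 85)  # 35-64, 65-74, 75-84, 85+
AGE_GROUP_LABELS = ("35-64", "65-74", "75-84", "85+")


def age_group_of(age_years: np.ndarray) -> np.ndarray:
    """Allocation age-group index for ages in years."""
    return np.searchsorted(np.asarray(AGE_GROUP_EDGES[1:]), age_years,
                           side="right")


@dataclass
class AllocationTable:
    """P(dementia) by (age_group, mmse_band, residence)."""

    table: pd.DataFrame  # columns: age_group, mmse_band, residence, p

    def __post_init__(self) -> None:
        t = self.table
        required = {"age_group", "mmse_band", "residence", "p"}
        if not required.issubset(t.columns):
            raise ConfigurationError(
                f"allocation table needs columns {sorted(required)}")
        if ((t["p"] < 0) | (t["p"] > 1)).any():
            raise ConfigurationError("allocation probability outside [0, 1]")
        # dense lookup p[age_group, band, residence]
        self._p = np.full((len(AGE_GROUP_LABELS), len(MMSE_BAND_LEVELS),
                           len(RESIDENCE_LEVELS)), np.nan)
        gi = {g: i for i, g in enumerate(AGE_GROUP_LABELS)}
        bi = {b: i for i, b in enumerate(MMSE_BAND_LEVELS)}
        ri = {r: i for i, r in enumerate(RESIDENCE_LEVELS)}
        for row in t.itertuples(index=False):
            try:
                self._p[gi[row.age_group], bi[row.mmse_band],
                        ri[row.residence]] = row.p
            except KeyError as exc:
                raise ConfigurationError(
                    f"unknown allocation cell label: {exc}") from None

    def lookup(self, age_years: np.ndarray, mmse_band: np.ndarray,
               residence: np.ndarray) -> np.ndarray:
        p = self._p[age_group_of(age_years), mmse_band, residence]
        if np.isnan(p).any():
            bad = np.flatnonzero(np.isnan(p))[0]
            raise TableCoverageError(
                "allocation table missing cell "
                f"(age_group={AGE_GROUP_LABELS[age_group_of(np.asarray(age_years)[bad:bad + 1])[0]]}, "
                f"mmse_band={MMSE_BAND_LEVELS[int(np.asarray(mmse_band)[bad])]}, "
                f"residence={RESIDENCE_LEVELS[int(np.asarray(residence)[bad])]})")
        return p

    @classmethod
    def from_csv(cls, path) -> "AllocationTable":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def default_allocation_table() -> AllocationTable:
    """Synthetic default: rises with age, low MMSE and care-home residence.

    This is a stand-in for the survey-derived allocation, which is
    unpublished; magnitudes are chosen to give an overall 65+ dementia
    prevalence of a few percent.
    """
    base = {  # by (age_group, mmse_band): community probability
        ("35-64", "normal"): 0.000, ("35-64", "mild"): 0.002,
        ("35-64", "impaired"): 0.02,
        ("65-74", "normal"): 0.002, ("65-74", "mild"): 0.02,
        ("65-74", "impaired"): 0.15,
        ("75-84", "normal"): 0.01, ("75-84", "mild"): 0.06,
        ("75-84", "impaired"): 0.35,
        ("85+", "normal"): 0.03, ("85+", "mild"): 0.15,
        ("85+", "impaired"): 0.60,
    }
    rows = []
    for (grp, band), p in base.items():
        rows.append((grp, band, "community", p))
        rows.append((grp, band, "care_home", min(1.0, 2.0 * p + 0.05)))
    return AllocationTable(pd.DataFrame(
        rows, columns=["age_group", "mmse_band", "residence", "p"]))


def allocate_dementia(output: SimulationOutput, table: AllocationTable,
                      seed: int, mode: str = "persistent",
                      ) -> SimulationOutput:
    """Set dementia flags on every snapshot of a run.

    ``mode='persistent'`` (default) draws one uniform quantile per
    individual for the whole run; ``mode='independent'`` redraws per
    snapshot.  Returns a new :class:`SimulationOutput`; input is untouched.
    """
    if mode not in ("persistent", "independent"):
        raise ConfigurationError(f"unknown allocation mode {mode!r}")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xD])
    all_ids = np.unique(np.concatenate(
        [snap["id"].to_numpy() for snap in output.snapshots.values()]))
    u_by_id = pd.Series(rng.random(len(all_ids)), index=all_ids)

    new_snaps = {}
    for year in sorted(output.snapshots):
        snap = output.snapshots[year].copy()
        band = np.asarray(mmse_band_from_score(snap["mmse"].to_numpy()))
        p = table.lookup(snap["age_months"].to_numpy() // 12, band,
                         snap["residence"].to_numpy())
        if mode == "persistent":
            u = u_by_id.loc[snap["id"].to_numpy()].to_numpy()
        else:
            u = rng.random(len(snap))
        snap["dementia"] = (u < p).astype(np.int64)
        new_snaps[year] = snap
    return SimulationOutput(snapshots=new_snaps, deaths=output.deaths,
                            replicate=output.replicate, seed=output.seed,
                            alive_counts=output.alive_counts)
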