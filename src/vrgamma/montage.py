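"""59-channel 10-10 montage with five scalp regions.

The montage mirrors a 64-channel wireless EEG cap after dropping the five
non-EEG channels (one cardiac, four ocular): 59 data electrodes grouped
into frontal (F), central-parietal (P), occipital (O), left-temporal (LT)
and right-temporal (RT) regions, plus the two three-channel prefrontal
subsets used for hemispheric-asymmetry contrasts.

The channel-to-region table ships as a versioned CSV
(``vrgamma/data/montage59.csv``) so the assignment is pinned and
reproducible; :func:`Montage.from_csv` lets a user substitute their own
table. Positions are unitless head-circle coordinates used only for
plotting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = ["Montage", "default_montage", "REGIONS"]

#: Region codes in the fixed order used by all downstream tables.
REGIONS: tuple[str, ...] = ("F", "P", "O", "LT", "RT")

#: Left / right prefrontal subsets for the asymmetry analysis.
LF_CHANNELS = frozenset({"Fp1", "AF3", "AF7"})
RF_CHANNELS = frozenset({"Fp2", "AF4", "AF8"})


@dataclass(frozen=True)
class Montage:
    """Ordered electrode set with scalp positions and region assignment.

    Attributes
    ----------
    channel_names : tuple of str
        Electrode labels in recording order (59 for the default montage).
    positions : ndarray, shape (n_channels, 2)
        Unitless 2-D head-circle coordinates (x = left-to-right,
        y = back-to-front).
    region_map : dict
        Total map ``channel -> region`` with regions drawn from
        :data:`REGIONS`.
    lf_set, rf_set : frozenset
        Left / right prefrontal channel subsets.
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray
    region_map: dict[str, str]
    lf_set: frozenset[str] = LF_CHANNELS
    rf_set: frozenset[str] = RF_CHANNELS

    def __post_init__(self) -> None:
        names = self.channel_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names in montage")
        missing = [c for c in names if c not in self.region_map]
        if missing:
            raise ValueError(f"channels without region assignment: {missing}")
        bad = {r for r in self.region_map.values()} - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region codes: {sorted(bad)}")
        if self.positions.shape != (len(names), 2):
            raise ValueError("positions must be (n_channels, 2)")
        for side, subset in (("lf", self.lf_set), ("rf", self.rf_set)):
            unknown = subset - set(names)
            if unknown:
                raise ValueError(f"{side}_set channels not in montage: {sorted(unknown)}")
        if self.lf_set & self.rf_set:
            raise ValueError("lf_set and rf_set must be disjoint")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, channel: str) -> int:
        return self.channel_names.index(channel)

    def region_channels(self, region: str) -> list[str]:
        """Channels belonging to ``region``, in montage order."""
        if region not in REGIONS:
            raise KeyError(f"unknown region {region!r}")
        return [c for c in self.channel_names if self.region_map[c] == region]

    def region_indices(self, region: str) -> np.ndarray:
        return np.array([self.index(c) for c in self.region_channels(region)], dtype=int)

    def subset_indices(self, channels) -> np.ndarray:
        return np.array([self.index(c) for c in sorted(channels, key=self.index)], dtype=int)

    @classmethod
    def from_csv(cls, path) -> "Montage":
        """Load a montage from a ``name,region,x,y`` CSV file."""
        names: list[str] = []
        regions: dict[str, str] = {}
        pos: list[tuple[float, float]] = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                names.append(row["name"])
                regions[row["name"]] = row["region"]
                pos.append((float(row["x"]), float(row["y"])))
        return cls(tuple(names), np.asarray(pos, dtype=float), regions)

    def plot(self, ax=None, annotate: bool = True):
        """Scatter the electrode layout on a head circle (matplotlib optional)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        colors = {"F": "tab:blue", "P": "tab:green", "O": "tab:orange",
                  "LT": "tab:red", "RT": "tab:purple"}
        for region in REGIONS:
            idx = self.region_indices(region)
            ax.scatter(self.positions[idx, 0], self.positions[idx, 1],
                       label=region, color=colors[region], s=30)
        if annotate:
            for name, (x, y) in zip(self.channel_names, self.positions):
                ax.annotate(name, (x, y), fontsize=6, ha="center", va="bottom")
        circle = plt.Circle((0, 0), 1.0, fill=False, color="k", lw=0.8)
        ax.add_patch(circle)
        ax.set_aspect("equal")
        ax.legend(loc="lower right", fontsize=7)
        ax.set_axis_off()
        return ax


def default_montage() -> Montage:
    """The pinned 59-channel montage shipped with the package."""
    ref = resources.files("vrgamma.data").joinpath("montage59.csv")
    with resources.as_file(ref) as path:
        return Montage.from_csv(path)
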