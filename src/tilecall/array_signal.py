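"""Array intensity normalization and per-tile log2 signal ratios.

For each strain, two test hybridizations (divergent DNA) and two reference
hybridizations (reference-strain DNA) are quantile-normalized together so
that all four arrays share one intensity distribution. The per-tile
signal is then the log2 ratio of the mean test intensity over the mean
reference intensity; strongly negative values indicate the tile's target
sequence is absent (or heavily diverged) in the test genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TEST = "test"
REFERENCE = "reference"


@dataclass
class IntensityTable:
    """Probes x arrays matrix of positive hybridization intensities.

    ``roles[j]`` labels column ``j`` as a test or reference hybridization.
    """

    probe_ids: list[str]
    labels: list[str]
    roles: list[str]
    values: np.ndarray  # shape (n_probes, n_arrays)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_probes, n_arrays = self.values.shape
        if len(self.probe_ids) != n_probes:
            raise ValueError("probe_ids length does not match value rows")
        if len(self.labels) != n_arrays or len(self.roles) != n_arrays:
            raise ValueError("labels/roles length does not match value columns")
        bad = set(self.roles) - {TEST, REFERENCE}
        if bad:
            raise ValueError(f"unknown array roles: {sorted(bad)}")
        if TEST not in self.roles or REFERENCE not in self.roles:
            raise ValueError("need at least one test and one reference array")
        finite = np.isfinite(self.values)
        positive = self.values > 0
        if not (finite & positive).all():
            i, j = np.argwhere(~(finite & positive))[0]
            raise ValueError(
                f"non-positive or non-finite intensity for probe "
                f"{self.probe_ids[i]!r} in array {self.labels[j]!r}"
            )

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    def columns(self, role: str) -> np.ndarray:
        """Sub-matrix of the columns with the given role."""
        idx = [j for j, r in enumerate(self.roles) if r == role]
        return self.values[:, idx]

    @classmethod
    def from_tsvs(
        cls,
        test_paths: Sequence[str | Path],
        reference_paths: Sequence[str | Path],
    ) -> "IntensityTable":
        """Assemble a table from per-array `probe_id<TAB>intensity` TSVs.

        Probes are intersected across arrays; row order follows the first file.
        """
        frames, labels, roles = [], [], []
        for role, paths in ((TEST, test_paths), (REFERENCE, reference_paths)):
            for p in paths:
                df = pd.read_csv(p, sep="\t", dtype={"probe_id": str})
                if list(df.columns) != ["probe_id", "intensity"]:
                    raise ValueError(
                        f"{p}: expected columns ['probe_id', 'intensity']"
                    )
                frames.append(df.set_index("probe_id")["intensity"])
                labels.append(Path(p).stem)
                roles.append(role)
        common = frames[0].index
        for s in frames[1:]:
            common = common.intersection(s.index)
        common_set = set(common)
        common = [pid for pid in frames[0].index if pid in common_set]
        values = np.column_stack([s.loc[common].to_numpy() for s in frames])
        return cls(list(common), labels, roles, values)


@dataclass
class SignalRatioTrack:
    """probe_id -> log2(test mean / reference mean), one entry per probe."""

    ratios: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ratios)

    def __getitem__(self, probe_id: str) -> float:
        return self.ratios[probe_id]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("probe_id\tratio\n")
            for pid, r in self.ratios.items():
                fh.write(f"{pid}\t{r:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignalRatioTrack":
        df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
        return cls(dict(zip(df["probe_id"], df["ratio"].astype(float))))

    def to_bedgraph(self, probes, path: str | Path) -> None:
        """Write ratios as bedGraph using tile coordinates from a ProbeMap."""
        with open(path, "w") as fh:
            for p in probes:
                if p.probe_id in self.ratios:
                    fh.write(
                        f"{p.chrom}\t{p.start}\t{p.end}\t"
                        f"{self.ratios[p.probe_id]:.6g}\n"
                    )


def quantile_normalize(table: IntensityTable) -> IntensityTable:
    """Force every array onto the common (rank-mean) intensity distribution.

    Each column's values are replaced by the across-array mean of the
    values at the same rank; ties within a column receive the mean of the
    reference quantiles over their tied rank span, so within-column rank
    order is preserved and the output multiset is identical in every
    column. Idempotent up to floating-point error.
    """
    X = table.values
    n = X.shape[0]
    # reference distribution: per-rank mean of the sorted columns
    means = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    from scipy.stats import rankdata

    grid = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")
        # fractional (tied) ranks interpolate between adjacent quantiles,
        # i.e. tied values get the mean of the quantiles they span
        out[:, j] = np.interp(ranks, grid, means)
    return IntensityTable(
        list(table.probe_ids), list(table.labels), list(table.roles), out
    )


def signal_ratio(table: IntensityTable) -> SignalRatioTrack:
    """Per-tile log2 ratio of mean test intensity over mean reference intensity.

    Normalization is the caller's responsibility; a warning is emitted if
    the column distributions differ materially (un-normalized input).
    """
    test = table.columns(TEST)
    ref = table.columns(REFERENCE)
    sorted_cols = np.sort(table.values, axis=0)
    spread = np.abs(sorted_cols - sorted_cols[:, :1])
    scale = max(np.abs(sorted_cols).max(), 1.0)
    # tolerance accommodates tie-induced perturbations of the multiset
    if spread.max() > 1e-3 * scale:
        warnings.warn(
            "array intensity distributions differ across columns; "
            "input does not look quantile-normalized",
            stacklevel=2,
        )
    test_mean = test.mean(axis=1)
    ref_mean = ref.mean(axis=1)
    if np.any(ref_mean == 0):
        i = int(np.argwhere(ref_mean == 0)[0][0])
        raise ValueError(
            f"zero reference mean for probe {table.probe_ids[i]!r}; cannot ratio"
        )
    ratios = np.log2(test_mean / ref_mean)
    return SignalRatioTrack(dict(zip(table.probe_ids, ratios.tolist())))
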