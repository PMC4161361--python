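"""Genetic maps, map-function arithmetic and the genome-wide locus grid.

A :class:`GeneticMap` holds, per chromosome, ordered marker names and positions
in centimorgans.  QTL scans evaluate putative loci on a regular grid laid over
the map (:class:`LocusGrid`); each grid locus knows its flanking markers so
conditional genotype probabilities can be computed from them.

Map distances are converted to recombination fractions with the Haldane map
function (no crossover interference), matching the independent-crossover model
used by the simulator.  Kosambi is available as an option but is never the
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Chromosome",
    "GeneticMap",
    "LocusGrid",
    "map_distance_to_recomb",
    "recomb_to_map_distance",
    "build_locus_grid",
    "cumulative_position",
    "invert_cumulative",
]


def map_distance_to_recomb(d_cM, function: str = "haldane"):
    """Convert a map distance in cM to a recombination fraction.

    Haldane: r = (1 - exp(-2 d)) / 2 with d in Morgans; Kosambi:
    r = tanh(2 d) / 2.  Vectorized over ``d_cM``.
    """
    d = np.asarray(d_cM, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise ValueError("map distance must be finite and non-negative")
    m = d / 100.0
    if function == "haldane":
        r = 0.5 * (1.0 - np.exp(-2.0 * m))
    elif function == "kosambi":
        r = 0.5 * np.tanh(2.0 * m)
    else:
        raise ValueError(f"unknown map function: {function!r}")
    if np.ndim(d_cM) == 0:
        return float(r)
    return r


def recomb_to_map_distance(r, function: str = "haldane"):
    """Inverse of :func:`map_distance_to_recomb` (cM)."""
    rr = np.asarray(r, dtype=float)
    if np.any(rr < 0) or np.any(rr >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    if function == "haldane":
        d = -50.0 * np.log(1.0 - 2.0 * rr)
    elif function == "kosambi":
        d = 25.0 * np.log((1.0 + 2.0 * rr) / (1.0 - 2.0 * rr))
    else:
        raise ValueError(f"unknown map function: {function!r}")
    if np.ndim(r) == 0:
        return float(d)
    return d


@dataclass(frozen=True)
class Chromosome:
    name: str
    marker_names: tuple
    marker_pos_cM: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.marker_pos_cM, dtype=float)
        object.__setattr__(self, "marker_pos_cM", pos)
        if len(self.marker_names) != pos.size:
            raise ValueError(f"chromosome {self.name}: name/position length mismatch")
        if pos.size < 2:
            raise ValueError(f"chromosome {self.name}: needs >= 2 markers")
        if np.any(~np.isfinite(pos)) or np.any(pos < 0):
            raise ValueError(f"chromosome {self.name}: positions must be finite and >= 0")
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"chromosome {self.name}: positions must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.marker_pos_cM[-1] - self.marker_pos_cM[0])

    @property
    def n_markers(self) -> int:
        return int(self.marker_pos_cM.size)


@dataclass(frozen=True)
class GeneticMap:
    chromosomes: tuple

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        all_markers = [m for c in self.chromosomes for m in c.marker_names]
        if len(set(all_markers)) != len(all_markers):
            raise ValueError("duplicate marker names across the map")

    @property
    def chrom_names(self):
        return [c.name for c in self.chromosomes]

    @property
    def marker_names(self):
        return [m for c in self.chromosomes for m in c.marker_names]

    @property
    def n_markers(self) -> int:
        return sum(c.n_markers for c in self.chromosomes)

    def chromosome(self, name) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome: {name!r}")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (m, c.name, p)
            for c in self.chromosomes
            for m, p in zip(c.marker_names, c.marker_pos_cM)
        ]
        return pd.DataFrame(rows, columns=["marker", "chrom", "pos_cM"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GeneticMap":
        required = {"marker", "chrom", "pos_cM"}
        if not required.issubset(df.columns):
            raise ValueError(f"map table must have columns {sorted(required)}")
        chroms = []
        for name, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("pos_cM", kind="stable")
            chroms.append(
                Chromosome(
                    name=str(name),
                    marker_names=tuple(str(m) for m in grp["marker"]),
                    marker_pos_cM=grp["pos_cM"].to_numpy(dtype=float),
                )
            )
        return cls(chromosomes=tuple(chroms))

    @classmethod
    def from_csv(cls, path) -> "GeneticMap":
        return cls.from_dataframe(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class LocusGrid:
    """Ordered genome-wide set of putative loci with flanking-marker indices.

    ``left_idx`` / ``right_idx`` index markers *within* the locus's chromosome;
    ``chrom_idx`` indexes chromosomes in the parent map.  ``cum_pos`` is the
    genome-wide coordinate: chromosome-local position plus the summed lengths
    of all preceding chromosomes.
    """

    gmap: GeneticMap
    chrom_idx: np.ndarray
    pos_cM: np.ndarray
    left_idx: np.ndarray
    right_idx: np.ndarray
    at_marker: np.ndarray
    step_cM: float
    cum_pos: np.ndarray = field(init=False)
    marker_col: np.ndarray = field(init=False)

    def __post_init__(self):
        offsets = _chrom_offsets(self.gmap)
        self.cum_pos = self.pos_cM + offsets[self.chrom_idx]
        # global marker-column index for loci sitting exactly on a marker, else -1
        starts = np.concatenate(
            [[0], np.cumsum([c.n_markers for c in self.gmap.chromosomes])[:-1]]
        )
        col = np.full(self.pos_cM.size, -1, dtype=int)
        at = self.at_marker
        col[at] = starts[self.chrom_idx[at]] + self.left_idx[at]
        self.marker_col = col

    def __len__(self) -> int:
        return int(self.pos_cM.size)

    @property
    def chrom_names(self):
        names = np.asarray(self.gmap.chrom_names, dtype=object)
        return names[self.chrom_idx]

    def interval_id(self) -> np.ndarray:
        """Marker-interval label per locus, unique genome-wide.

        Interior loci belong to the interval [left marker, right marker); a
        locus sitting on a marker is assigned the interval starting at that
        marker (the terminal marker of a chromosome joins the last interval).
        """
        n_mark = np.asarray([c.n_markers for c in self.gmap.chromosomes])
        iv = np.minimum(self.left_idx, n_mark[self.chrom_idx] - 2)
        # offset so that intervals are unique across chromosomes
        iv_offsets = np.concatenate([[0], np.cumsum(n_mark - 1)[:-1]])
        return iv + iv_offsets[self.chrom_idx]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom_names,
                "pos_cM": self.pos_cM,
                "genome_pos_cM": self.cum_pos,
                "left_idx": self.left_idx,
                "right_idx": self.right_idx,
                "at_marker": self.at_marker,
            }
        )


def _chrom_offsets(gmap: GeneticMap) -> np.ndarray:
    lengths = np.asarray([c.length for c in gmap.chromosomes])
    return np.concatenate([[0.0], np.cumsum(lengths)[:-1]])


def build_locus_grid(gmap: GeneticMap, step_cM: float = 1.0) -> LocusGrid:
    """Lay a regular grid over the map: every marker plus interior points at
    multiples of ``step_cM`` from each chromosome's first marker."""
    if not np.isfinite(step_cM) or step_cM <= 0:
        raise ValueError("step_cM must be positive and finite")
    chrom_idx, pos, left, right, at_marker = [], [], [], [], []
    for ci, chrom in enumerate(gmap.chromosomes):
        mpos = chrom.marker_pos_cM
        start, end = mpos[0], mpos[-1]
        n_steps = int(np.floor((end - start) / step_cM + 1e-9))
        stepped = start + step_cM * np.arange(n_steps + 1)
        allpos = np.union1d(np.round(stepped, 9), np.round(mpos, 9))
        allpos = allpos[(allpos >= start - 1e-9) & (allpos <= end + 1e-9)]
        # snap to marker positions where they coincide numerically
        for p in allpos:
            j = int(np.searchsorted(mpos, p + 1e-9)) - 1
            j = max(j, 0)
            if abs(p - mpos[j]) < 1e-6:
                li = ri = j
                p = mpos[j]
            elif j + 1 < mpos.size and abs(p - mpos[j + 1]) < 1e-6:
                li = ri = j + 1
                p = mpos[j + 1]
            else:
                li, ri = j, j + 1
            chrom_idx.append(ci)
            pos.append(p)
            left.append(li)
            right.append(ri)
            at_marker.append(li == ri)
    return LocusGrid(
        gmap=gmap,
        chrom_idx=np.asarray(chrom_idx, dtype=int),
        pos_cM=np.asarray(pos, dtype=float),
        left_idx=np.asarray(left, dtype=int),
        right_idx=np.asarray(right, dtype=int),
        at_marker=np.asarray(at_marker, dtype=bool),
        step_cM=float(step_cM),
    )


def cumulative_position(gmap: GeneticMap, chrom_name, pos_cM: float) -> float:
    """Genome-wide coordinate of a chromosome-local position."""
    offsets = _chrom_offsets(gmap)
    for ci, c in enumerate(gmap.chromosomes):
        if c.name == chrom_name:
            if not (c.marker_pos_cM[0] - 1e-9 <= pos_cM <= c.marker_pos_cM[-1] + 1e-9):
                raise ValueError(
                    f"position {pos_cM} outside chromosome {chrom_name} span "
                    f"[{c.marker_pos_cM[0]}, {c.marker_pos_cM[-1]}]"
                )
            return float(offsets[ci] + (pos_cM - c.marker_pos_cM[0]))
    raise KeyError(f"unknown chromosome: {chrom_name!r}")


def invert_cumulative(gmap: GeneticMap, genome_pos_cM: float):
    """Map a genome-wide coordinate back to (chrom_name, local position)."""
    offsets = _chrom_offsets(gmap)
    total = offsets[-1] + gmap.chromosomes[-1].length
    if not (-1e-9 <= genome_pos_cM <= total + 1e-9):
        raise ValueError(f"genome position {genome_pos_cM} outside [0, {total}]")
    ci = int(np.searchsorted(offsets, genome_pos_cM + 1e-9)) - 1
    ci = min(max(ci, 0), len(gmap.chromosomes) - 1)
    chrom = gmap.chromosomes[ci]
    local = genome_pos_cM - offsets[ci] + chrom.marker_pos_cM[0]
    return chrom.name, float(local)
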