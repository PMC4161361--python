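"""CSV readers/writers and run configuration.

File formats (all UTF-8, comma-separated, header row mandatory):

* map CSV: ``marker,chrom,pos_cM`` (any order; sorted internally);
* genotype CSV: first column the individual id, remaining columns one marker
  each, codes ``A``/``H`` for the two-class designs (mapped to -1/+1) and
  ``A``/``H``/``B`` for an F2 (allele counts 0/1/2); missing is ``-``, ``NA``
  or an empty cell; numeric codes are also accepted;
* phenotype CSV: ``id,phenotype`` with an optional ``trials`` column for
  binomial traits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genmap import GeneticMap

__all__ = ["CrossData", "RunConfig", "read_cross", "write_cross"]

_MISSING = {"-", "NA", "", "nan", "NaN"}
_TWO_CLASS = {"A": -1.0, "H": 1.0, "B": 1.0, "-1": -1.0, "1": 1.0, "+1": 1.0}
_F2_CLASS = {"A": 0.0, "H": 1.0, "B": 2.0, "0": 0.0, "1": 1.0, "2": 2.0, "-1": 0.0}


@dataclass
class CrossData:
    gmap: GeneticMap
    ids: list
    genotypes: np.ndarray      # n x m, coded, NaN = missing
    phenotypes: np.ndarray
    design: str
    trials: np.ndarray | None = None


def _decode_genotypes(df: pd.DataFrame, design: str) -> np.ndarray:
    table = _F2_CLASS if design == "F2" else _TWO_CLASS
    out = np.full(df.shape, np.nan)
    values = df.to_numpy(dtype=object)
    for (i, j), raw in np.ndenumerate(values):
        s = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
        if s in _MISSING:
            continue
        if s.endswith(".0"):
            s = s[:-2]
        if s not in table:
            raise ValueError(
                f"invalid genotype code {s!r} for individual row {i}, marker "
                f"{df.columns[j]!r} (design {design})"
            )
        out[i, j] = table[s]
    return out


def read_cross(map_csv, genotype_csv, phenotype_csv, design="backcross",
               family_name=None) -> CrossData:
    """Read and cross-validate a map, genotype matrix and phenotype table."""
    gmap = GeneticMap.from_csv(map_csv)
    gdf = pd.read_csv(genotype_csv, dtype=object)
    if gdf.shape[1] < 2:
        raise ValueError("genotype CSV needs an id column plus marker columns")
    id_col = gdf.columns[0]
    ids = [str(v) for v in gdf[id_col]]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids in the genotype table")
    geno_markers = list(gdf.columns[1:])
    map_markers = gmap.marker_names
    missing_from_map = [m for m in geno_markers if m not in set(map_markers)]
    if missing_from_map:
        raise ValueError(f"genotype column(s) absent from the map: {missing_from_map}")
    missing_from_geno = [m for m in map_markers if m not in set(geno_markers)]
    if missing_from_geno:
        raise ValueError(f"map marker(s) absent from the genotype table: {missing_from_geno}")
    gdf = gdf[[id_col] + map_markers]  # align to map order
    genotypes = _decode_genotypes(gdf[map_markers], design)

    pdf = pd.read_csv(phenotype_csv)
    if pdf.shape[1] < 2:
        raise ValueError("phenotype CSV needs an id column plus a phenotype column")
    pid_col = pdf.columns[0]
    pids = [str(v) for v in pdf[pid_col]]
    if len(set(pids)) != len(pids):
        raise ValueError("duplicate individual ids in the phenotype table")
    if set(pids) != set(ids):
        raise ValueError("phenotype and genotype tables cover different individuals")
    pdf = pdf.set_index(pid_col).loc[[str(i) for i in ids]]
    y = pdf.iloc[:, 0].to_numpy(dtype=float)
    trials = None
    if "trials" in pdf.columns:
        trials = pdf["trials"].to_numpy(dtype=float)
        if np.any(trials < 1):
            raise ValueError("trial counts must be >= 1")
        y = y / trials  # counts -> proportions
    if family_name == "poisson":
        bad = np.flatnonzero((y < 0) | (np.abs(y - np.round(y)) > 1e-8))
        if bad.size:
            raise ValueError(
                f"non-integer or negative Poisson phenotype at row {bad[0]} (id {ids[bad[0]]})"
            )
    if family_name == "binomial" and trials is None:
        bad = np.flatnonzero(~np.isin(y, (0.0, 1.0)))
        if bad.size:
            raise ValueError(
                f"binary phenotype outside {{0, 1}} at row {bad[0]} (id {ids[bad[0]]})"
            )
    return CrossData(gmap=gmap, ids=ids, genotypes=genotypes, phenotypes=y,
                     design=design, trials=trials)


def write_cross(out_dir, gmap: GeneticMap, ids, genotypes, phenotypes, design="backcross",
                trials=None, truth=None):
    """Write map/genotype/phenotype CSVs (and an optional truth JSON).

    Returns the paths written.  Genotypes are encoded with the letter codes
    accepted by :func:`read_cross`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    map_path = out / "map.csv"
    gmap.to_csv(map_path)
    G = np.asarray(genotypes, dtype=float)
    if design == "F2":
        codes = {0.0: "A", 1.0: "H", 2.0: "B", -1.0: "A"}
    else:
        codes = {-1.0: "A", 1.0: "H"}
    enc = np.full(G.shape, "-", dtype=object)
    for val, letter in codes.items():
        enc[G == val] = letter
    gdf = pd.DataFrame(enc, columns=gmap.marker_names)
    gdf.insert(0, "id", list(ids))
    geno_path = out / "genotypes.csv"
    gdf.to_csv(geno_path, index=False)
    y = np.asarray(phenotypes, dtype=float)
    pdf = pd.DataFrame({"id": list(ids), "phenotype": y})
    if trials is not None:
        pdf["phenotype"] = np.round(y * np.asarray(trials)).astype(int)
        pdf["trials"] = np.asarray(trials).astype(int)
    pheno_path = out / "phenotypes.csv"
    pdf.to_csv(pheno_path, index=False)
    paths = {"map": map_path, "genotypes": geno_path, "phenotypes": pheno_path}
    if truth is not None:
        truth_path = out / "truth.json"
        truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
        paths["truth"] = truth_path
    return paths


@dataclass
class RunConfig:
    """Serializable description of a scan run; a run is reproducible from the
    config plus its seed alone."""

    map_csv: str = ""
    genotype_csv: str = ""
    phenotype_csv: str = ""
    out_dir: str = "."
    design: str = "backcross"
    family: str = "binomial"
    link: str | None = None
    grid_step: float = 1.0
    mode: str = "weighted"
    cv: str = "kfold"
    cv_folds: int = 5
    lam: float | None = None
    threshold_method: str = "null_simulation"
    threshold_replicates: int = 1000
    level: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
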