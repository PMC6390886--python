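"""Delimited-text readers/writers, marker QC and run configuration.

All tabular artefacts are plain tab-separated text with a header row and an
optional commented (``#``) provenance block, since no standard interchange
format exists for tetraploid IBD tables.  Gamete-class probabilities are
stored long (individual, chromosome, position, parent, class, probability);
dosage grids long as (individual, chromosome, position, homologue, dosage).

Marker QC reproduces SNP-array filtering for a tetraploid F1: markers with
too many missing calls, individuals with too many missing markers, and
markers whose offspring dosage counts are skewed relative to the tetrasomic
segregation expectation of their parental dosage pair (chi-square
goodness-of-fit; e.g. simplex x nulliplex segregates 1:1, duplex x
nulliplex 1:4:1) are removed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from .genmap import GeneticMap
from .ibd import GAMETE_CLASSES, GameteClassProbabilities, HomologueDosageGrid

__all__ = [
    "DosageMatrix",
    "RunConfig",
    "gamete_dosage_distribution",
    "expected_segregation",
    "qc_markers",
    "read_map_table",
    "write_map_table",
    "read_probabilities",
    "write_probabilities",
    "read_dosage_grid",
    "write_dosage_grid",
    "read_phenotypes",
    "write_table",
]


# ---------------------------------------------------------------------------
# marker QC

@dataclass
class DosageMatrix:
    """Integer SNP dosage calls for an F1 population.

    ``calls`` is a markers x individuals DataFrame with values 0..4 and NaN
    for missing; ``parents`` maps each marker to the two parental dosages
    (columns ``p1`` and ``p2``).
    """

    calls: pd.DataFrame
    parents: pd.DataFrame

    def __post_init__(self):
        if not set(self.parents.columns) >= {"p1", "p2"}:
            raise ValueError("parents table needs columns p1 and p2")
        missing = self.calls.index.difference(self.parents.index)
        if len(missing):
            raise ValueError(
                f"parental dosages missing for markers {list(missing[:3])}"
            )
        values = self.calls.to_numpy(dtype=float)
        ok = np.isnan(values) | ((values >= 0) & (values <= 4))
        if not ok.all():
            raise ValueError("dosage calls must be in 0..4 or missing")


def gamete_dosage_distribution(parent_dosage: int) -> np.ndarray:
    """P(gamete allele count = 0, 1, 2) for a tetraploid parent.

    Random bivalent pairing transmits 2 of the 4 homologues without
    replacement, so the count is hypergeometric(4, dosage, 2).
    """
    if parent_dosage not in range(5):
        raise ValueError("parental dosage must be in 0..4")
    return np.array(
        [
            math.comb(parent_dosage, k) * math.comb(4 - parent_dosage, 2 - k)
            / math.comb(4, 2)
            for k in range(3)
        ]
    )


def expected_segregation(p1: int, p2: int) -> np.ndarray:
    """Expected offspring dosage distribution (length 5) for a marker.

    Convolution of the two parental gamete distributions under bivalent
    meiosis: simplex x nulliplex gives 1:1 over dosages 0:1, duplex x
    nulliplex 1:4:1 over 0:1:2, and so on.
    """
    g1 = gamete_dosage_distribution(p1)
    g2 = gamete_dosage_distribution(p2)
    return np.convolve(g1, g2)


def qc_markers(
    dosages: DosageMatrix,
    max_marker_missing: float = 0.05,
    max_indiv_missing: float = 0.10,
    seg_alpha: float = 0.001,
) -> tuple:
    """Filter a dosage matrix and report why markers/individuals dropped.

    Order of operations: (1) markers above the missing-call threshold are
    dropped, (2) individuals above their missing threshold are dropped,
    (3) remaining markers are chi-square tested against the tetrasomic
    segregation expectation of their parental dosage pair and dropped when
    the goodness-of-fit P-value falls below ``seg_alpha``.

    Returns ``(filtered DosageMatrix, report DataFrame)``.
    """
    calls = dosages.calls
    report = []

    marker_missing = calls.isna().mean(axis=1)
    for marker in calls.index[marker_missing > max_marker_missing]:
        report.append(
            {
                "item": marker,
                "kind": "marker",
                "reason": "missing_rate",
                "value": marker_missing[marker],
            }
        )
    calls = calls.loc[marker_missing <= max_marker_missing]

    indiv_missing = calls.isna().mean(axis=0)
    for indiv in calls.columns[indiv_missing > max_indiv_missing]:
        report.append(
            {
                "item": indiv,
                "kind": "individual",
                "reason": "missing_rate",
                "value": indiv_missing[indiv],
            }
        )
    calls = calls.loc[:, indiv_missing <= max_indiv_missing]

    keep = []
    for marker in calls.index:
        p1 = int(dosages.parents.loc[marker, "p1"])
        p2 = int(dosages.parents.loc[marker, "p2"])
        expected = expected_segregation(p1, p2)
        observed = (
            calls.loc[marker]
            .dropna()
            .astype(int)
            .value_counts()
            .reindex(range(5), fill_value=0)
            .to_numpy(dtype=float)
        )
        support = expected > 0
        if observed[~support].sum() > 0:
            pval = 0.0  # impossible dosage class observed
        elif support.sum() < 2:
            pval = 1.0  # monomorphic expectation, nothing to test
        else:
            n = observed[support].sum()
            _, pval = scipy.stats.chisquare(
                observed[support], expected[support] * n
            )
        if pval < seg_alpha:
            report.append(
                {
                    "item": marker,
                    "kind": "marker",
                    "reason": "segregation",
                    "value": pval,
                }
            )
        else:
            keep.append(marker)
    calls = calls.loc[keep]
    filtered = DosageMatrix(
        calls=calls, parents=dosages.parents.loc[calls.index]
    )
    return filtered, pd.DataFrame(
        report, columns=["item", "kind", "reason", "value"]
    )


# ---------------------------------------------------------------------------
# tabular IO

def _read_tsv(path, required, name):
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} file {path} lacks columns {missing}")
    return df


def write_table(df: pd.DataFrame, path, header_lines=()) -> None:
    """Write a tidy TSV with an optional commented provenance block."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_map_table(gmap: GeneticMap, path) -> None:
    df = pd.DataFrame(
        {
            "chromosome": [n for n, _ in gmap.chromosomes],
            "length_cM": [l for _, l in gmap.chromosomes],
        }
    )
    write_table(df, path, header_lines=[f"grid_step_cM: {gmap.grid_step}"])


def read_map_table(path) -> GeneticMap:
    """Read a map as either chromosome lengths or marker positions."""
    step = 1.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "grid_step_cM:" in line:
                step = float(line.split(":", 1)[1])
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    if "length_cM" in df.columns:
        chroms = [(r["chromosome"], r["length_cM"]) for _, r in df.iterrows()]
    elif {"chromosome", "position"} <= set(df.columns):
        chroms = [
            (c, sub["position"].max())
            for c, sub in df.groupby("chromosome", sort=False)
        ]
    else:
        raise ValueError(
            f"map file {path} lacks columns: need chromosome + length_cM "
            "or chromosome + position"
        )
    return GeneticMap(chromosomes=tuple(chroms), grid_step=step)


def write_probabilities(probs: GameteClassProbabilities, path) -> None:
    """Write gamete-class probabilities in long format."""
    n, npos = probs.n_individuals, probs.n_positions
    chrom = probs.positions["chromosome"].to_numpy()
    pos = probs.positions["position"].to_numpy()
    frames = []
    for parent in (0, 1):
        block = probs.probs[:, :, parent, :]
        nz = np.argwhere(block > 0)
        frames.append(
            pd.DataFrame(
                {
                    "individual": probs.individuals[nz[:, 0]],
                    "chromosome": chrom[nz[:, 1]],
                    "position": pos[nz[:, 1]],
                    "parent": parent + 1,
                    "class": np.asarray(GAMETE_CLASSES)[nz[:, 2]],
                    "probability": block[nz[:, 0], nz[:, 1], nz[:, 2]],
                }
            )
        )
    write_table(pd.concat(frames, ignore_index=True), path)


def read_probabilities(path) -> GameteClassProbabilities:
    req = ["individual", "chromosome", "position", "parent", "class", "probability"]
    df = _read_tsv(path, req, "probability")
    df["class"] = df["class"].astype(str).str.zfill(2)
    bad = ~df["class"].isin(GAMETE_CLASSES)
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(f"unknown gamete class at data row {row}")
    individuals = np.asarray(pd.unique(df["individual"]))
    positions = (
        df[["chromosome", "position"]]
        .drop_duplicates()
        .sort_values(["chromosome", "position"], kind="stable")
        .reset_index(drop=True)
    )
    # stable ordering: keep chromosome order of first appearance
    chrom_order = {c: i for i, c in enumerate(pd.unique(df["chromosome"]))}
    positions = positions.sort_values(
        ["chromosome", "position"],
        key=lambda s: s.map(chrom_order) if s.name == "chromosome" else s,
        kind="stable",
    ).reset_index(drop=True)
    ind_idx = {v: i for i, v in enumerate(individuals)}
    pos_idx = {
        (r["chromosome"], r["position"]): i for i, r in positions.iterrows()
    }
    cls_idx = {c: i for i, c in enumerate(GAMETE_CLASSES)}
    probs = np.zeros((len(individuals), len(positions), 2, 10))
    probs[
        df["individual"].map(ind_idx).to_numpy(),
        [pos_idx[k] for k in zip(df["chromosome"], df["position"])],
        df["parent"].to_numpy(dtype=int) - 1,
        df["class"].map(cls_idx).to_numpy(),
    ] = df["probability"].to_numpy()
    sums = probs.sum(axis=3)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = np.argwhere(~np.isclose(sums, 1.0, atol=1e-6))[0]
        raise ValueError(
            f"probabilities for individual {individuals[bad[0]]!r}, "
            f"position index {bad[1]}, parent {bad[2] + 1} do not sum to 1"
        )
    return GameteClassProbabilities(
        probs=probs, positions=positions, individuals=individuals
    )


def write_dosage_grid(grid: HomologueDosageGrid, path) -> None:
    n, npos, _ = grid.X.shape
    chrom = np.tile(grid.positions["chromosome"].to_numpy(), n)
    pos = np.tile(grid.positions["position"].to_numpy(), n)
    ind = np.repeat(grid.individuals, npos)
    wide = pd.DataFrame(
        {"individual": ind, "chromosome": chrom, "position": pos}
    )
    for h in range(8):
        wide[f"X{h + 1}"] = grid.X[:, :, h].reshape(-1)
    write_table(wide, path)


def read_dosage_grid(path) -> HomologueDosageGrid:
    req = ["individual", "chromosome", "position"] + [f"X{h}" for h in range(1, 9)]
    df = _read_tsv(path, req, "dosage")
    individuals = np.asarray(pd.unique(df["individual"]))
    positions = df.loc[
        df["individual"] == individuals[0], ["chromosome", "position"]
    ].reset_index(drop=True)
    npos = len(positions)
    if len(df) != npos * len(individuals):
        raise ValueError("dosage table is not rectangular")
    X = (
        df[[f"X{h}" for h in range(1, 9)]]
        .to_numpy()
        .reshape(len(individuals), npos, 8)
    )
    return HomologueDosageGrid(X=X, positions=positions, individuals=individuals)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype trial table; derives the trait when raw columns
    (pfj_protein, dry_matter) are present but protein_content is not."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("clone", "year", "block"):
        if col not in df.columns:
            raise ValueError(f"phenotype file {path} lacks column {col!r}")
    if "protein_content" not in df.columns:
        if {"pfj_protein", "dry_matter"} <= set(df.columns):
            from .pheno import derive_trait

            df = derive_trait(df)
        else:
            raise ValueError(
                f"phenotype file {path} lacks protein_content (or "
                "pfj_protein + dry_matter to derive it)"
            )
    return df


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Configuration of a simulation/analysis run; round-trips via YAML."""

    seed: int = 1
    grid_step: float = 1.0
    n_perm: int = 1000
    alpha: float = 0.05
    n_individuals: int = 496
    chromosomes: list = field(default_factory=lambda: [["chr1", 100.0]])
    quadrivalent_rate: float = 0.0
    double_reduction_rate: float = 0.0
    informativeness: float = 1.0
    years: int = 1
    blocks_per_year: int = 2
    var_G_polygenic: float = 0.042
    var_GxY: float = 0.001
    var_E: float = 0.062
    qtl: dict | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
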