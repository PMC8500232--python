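"""Data model and deterministic transforms for floral-scent studies.

A study consists of a wide scent matrix (samples x compounds, absolute
emission in ng inflorescence^-1 h^-1), per-sample metadata (population,
region, sample type), a compound-descriptor table (Kovats retention index,
name, compound class), and per-individual fruit counts used as a female
fitness proxy.  This module holds the containers, delimited-text readers and
writers, and the deterministic transforms every downstream analysis relies
on: compound filtering against negative controls, conversion to relative
(percent) amounts, per-sample emission totals and richness, percentage and
population-relative fruit set, and z-standardisation of trait columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

COMPOUND_CLASSES = frozenset(
    {
        "aliphatic",
        "aromatic",
        "C5-branched",
        "nitrogen-bearing",
        "irregular terpene",
        "monoterpenoid",
        "sesquiterpenoid",
        "unknown",
    }
)

SAMPLE_TYPES = frozenset({"inflorescence", "leaf_control", "air_control"})
REGIONS = frozenset({"north", "south"})


class StudyValidationError(ValueError):
    """Raised when a study table violates a structural invariant."""


@dataclass
class ScentMatrix:
    """Samples x compounds amount matrix.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by sample id, columns by compound id.  Non-negative.
    mode : {"absolute", "relative"}
        Absolute amounts (ng inflorescence^-1 h^-1) or percent of the
        per-sample total (rows sum to 100).
    """

    values: pd.DataFrame
    mode: str = "absolute"

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "relative"):
            raise StudyValidationError(f"unknown mode {self.mode!r}")
        self.values.index.name = "sample_id"
        self.values.columns.name = "compound_id"
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise StudyValidationError(f"duplicate sample id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise StudyValidationError(f"duplicate compound id {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise StudyValidationError("scent matrix contains missing values")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise StudyValidationError(
                f"negative amount for sample {self.values.index[i]!r}, "
                f"compound {self.values.columns[j]!r}"
            )
        if self.mode == "relative":
            totals = arr.sum(axis=1)
            if not np.allclose(totals, 100.0, atol=1e-9):
                bad = self.values.index[np.argmax(np.abs(totals - 100.0))]
                raise StudyValidationError(
                    f"relative-mode row {bad!r} does not sum to 100"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ScentMatrix":
        return ScentMatrix(self.values.loc[list(sample_ids)].copy(), self.mode)

    def subset_compounds(self, compound_ids: Sequence[str]) -> "ScentMatrix":
        return ScentMatrix(self.values[list(compound_ids)].copy(), self.mode)

    def detection_rates(self) -> pd.Series:
        """Fraction of samples with a nonzero amount, per compound."""
        return (self.values > 0).mean(axis=0)


@dataclass
class Study:
    """A joined, validated study: scent + metadata + descriptors + fitness."""

    scent: ScentMatrix
    samples: pd.DataFrame
    descriptors: pd.DataFrame
    fitness: pd.DataFrame | None = None

    def inflorescence(self) -> ScentMatrix:
        ids = self.samples.loc[
            self.samples["sample_type"] == "inflorescence"
        ].index
        return self.scent.subset_samples([s for s in self.scent.sample_ids if s in set(ids)])

    def controls(self) -> ScentMatrix:
        ids = set(
            self.samples.loc[self.samples["sample_type"] != "inflorescence"].index
        )
        keep = [s for s in self.scent.sample_ids if s in ids]
        return self.scent.subset_samples(keep)


def _read_delim(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "population", "region", "sample_type"}
    missing = required - set(samples.columns)
    if missing:
        raise StudyValidationError(f"sample metadata missing columns {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise StudyValidationError(f"duplicate sample id {dup!r} in metadata")
    bad_region = set(samples["region"]) - REGIONS
    if bad_region:
        raise StudyValidationError(f"unknown region(s) {sorted(bad_region)}")
    bad_type = set(samples["sample_type"]) - SAMPLE_TYPES
    if bad_type:
        raise StudyValidationError(f"unknown sample type(s) {sorted(bad_type)}")
    # each population must map to exactly one region
    n_regions = samples.groupby("population")["region"].nunique()
    split = n_regions[n_regions > 1]
    if len(split):
        raise StudyValidationError(
            f"population(s) {list(split.index)} assigned to more than one region"
        )
    return samples.set_index("sample_id")


def validate_descriptors(desc: pd.DataFrame) -> pd.DataFrame:
    required = {"compound_id", "name", "kri", "compound_class", "verified"}
    missing = required - set(desc.columns)
    if missing:
        raise StudyValidationError(f"descriptor table missing columns {sorted(missing)}")
    if desc["compound_id"].duplicated().any():
        dup = desc.loc[desc["compound_id"].duplicated(), "compound_id"].iloc[0]
        raise StudyValidationError(f"duplicate compound id {dup!r} in descriptors")
    if (desc["kri"] <= 0).any():
        bad = desc.loc[desc["kri"] <= 0, "compound_id"].iloc[0]
        raise StudyValidationError(f"non-positive Kovats index for {bad!r}")
    bad_class = set(desc["compound_class"]) - COMPOUND_CLASSES
    if bad_class:
        raise StudyValidationError(f"unknown compound class(es) {sorted(bad_class)}")
    unk = desc.loc[desc["name"].astype(str).str.startswith("UNK")]
    for _, row in unk.iterrows():
        if str(row["name"]) != f"UNK{int(row['kri'])}":
            raise StudyValidationError(
                f"unknown compound {row['compound_id']!r} must be named "
                f"UNK{int(row['kri'])}, got {row['name']!r}"
            )
    return desc.set_index("compound_id")


def validate_fitness(fit: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "n_fruits", "n_flowers"}
    missing = required - set(fit.columns)
    if missing:
        raise StudyValidationError(f"fitness table missing columns {sorted(missing)}")
    if fit["sample_id"].duplicated().any():
        dup = fit.loc[fit["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise StudyValidationError(f"duplicate sample id {dup!r} in fitness table")
    bad = fit.loc[(fit["n_fruits"] < 0) | (fit["n_fruits"] > fit["n_flowers"])]
    if len(bad):
        raise StudyValidationError(
            f"sample {bad['sample_id'].iloc[0]!r} has n_fruits outside "
            f"[0, n_flowers]"
        )
    out = fit.set_index("sample_id").copy()
    out["pct_fruit_set"] = fruit_set_pct(
        out["n_fruits"].to_numpy(), out["n_flowers"].to_numpy()
    )
    return out


def load_study(
    scent_path: str | Path,
    descriptor_path: str | Path,
    fitness_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
) -> Study:
    """Read and join a study from delimited-text files.

    The scent file's first column is the sample id; remaining columns are one
    per compound id; a missing cell means non-detect (zero).  Compound columns
    not present in the descriptor table are rejected.
    """
    raw = _read_delim(scent_path)
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "sample_id"
    raw = raw.fillna(0.0)
    scent = ScentMatrix(raw.astype(float), mode="absolute")

    descriptors = validate_descriptors(_read_delim(descriptor_path))
    unknown_cols = set(scent.compound_ids) - set(descriptors.index)
    if unknown_cols:
        raise StudyValidationError(
            f"scent matrix contains undescribed compound(s) {sorted(unknown_cols)}"
        )

    samples = None
    if metadata_path is not None:
        samples = validate_samples(_read_delim(metadata_path))
        missing = set(scent.sample_ids) - set(samples.index)
        if missing:
            raise StudyValidationError(
                f"scent samples missing from metadata: {sorted(missing)}"
            )
        samples = samples.loc[scent.sample_ids]
    else:
        samples = pd.DataFrame(
            {
                "population": "ALL",
                "region": "north",
                "sample_type": "inflorescence",
                "year": 0,
            },
            index=pd.Index(scent.sample_ids, name="sample_id"),
        )

    fitness = None
    if fitness_path is not None:
        fitness = validate_fitness(_read_delim(fitness_path))
        stray = set(fitness.index) - set(scent.sample_ids)
        if stray:
            raise StudyValidationError(
                f"fitness records for unknown sample(s) {sorted(stray)}"
            )
        ctrl = samples.loc[samples["sample_type"] != "inflorescence"]
        with_fitness = set(fitness.index) & set(ctrl.index)
        if with_fitness:
            raise StudyValidationError(
                f"control sample(s) {sorted(with_fitness)} carry fitness data"
            )

    return Study(scent=scent, samples=samples, descriptors=descriptors, fitness=fitness)


def write_study(study: Study, out_dir: str | Path) -> dict[str, Path]:
    """Write a study back to the delimited-text dialect `load_study` reads.

    Round-trips bit-identically: write -> load -> write produces the same
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "scent": out / "scent.csv",
        "metadata": out / "samples.csv",
        "descriptors": out / "compounds.csv",
    }
    study.scent.values.to_csv(paths["scent"], float_format="%.10g")
    study.samples.reset_index().to_csv(paths["metadata"], index=False)
    study.descriptors.reset_index().to_csv(paths["descriptors"], index=False)
    if study.fitness is not None:
        paths["fitness"] = out / "fitness.csv"
        cols = ["n_fruits", "n_flowers"]
        study.fitness.reset_index()[["sample_id"] + cols].to_csv(
            paths["fitness"], index=False
        )
    return paths


def filter_compounds(
    matrix: ScentMatrix,
    controls: ScentMatrix | None = None,
    min_occurrence: int = 4,
) -> ScentMatrix:
    """Keep compounds occurring in >= `min_occurrence` inflorescence samples
    and absent from every control sample.

    The default of 4 reads "in more than three scent samples" literally; any
    nonzero amount in any leaf or air control disqualifies a compound.
    Column order is preserved and the operation is idempotent.
    """
    if matrix.mode != "absolute":
        raise StudyValidationError("filter_compounds requires an absolute-mode matrix")
    occ = (matrix.values > 0).sum(axis=0)
    keep = occ >= min_occurrence
    if controls is not None and controls.n_samples > 0:
        shared = [c for c in matrix.compound_ids if c in set(controls.compound_ids)]
        if set(shared) != set(matrix.compound_ids):
            raise StudyValidationError("controls do not cover all compound columns")
        in_controls = (controls.values[matrix.compound_ids] > 0).any(axis=0)
        keep &= ~in_controls
    kept = [c for c in matrix.compound_ids if keep[c]]
    return matrix.subset_compounds(kept)


def to_relative(matrix: ScentMatrix) -> ScentMatrix:
    """Convert absolute amounts to percent of each sample's total."""
    if matrix.mode != "absolute":
        raise StudyValidationError("to_relative requires an absolute-mode matrix")
    totals = matrix.values.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise StudyValidationError(f"sample {bad!r} has zero total emission")
    rel = matrix.values.div(totals, axis=0) * 100.0
    return ScentMatrix(rel, mode="relative")


def total_emission(matrix: ScentMatrix) -> pd.DataFrame:
    """Per-sample total emission and richness (nonzero-compound count)."""
    if matrix.mode != "absolute":
        raise StudyValidationError("total_emission requires an absolute-mode matrix")
    return pd.DataFrame(
        {
            "total": matrix.values.sum(axis=1),
            "richness": (matrix.values > 0).sum(axis=1),
        }
    )


def fruit_set_pct(n_fruits, n_flowers):
    """Percentage fruit set: 100 * fruits / flowers per individual."""
    n_fruits = np.asarray(n_fruits, dtype=float)
    n_flowers = np.asarray(n_flowers, dtype=float)
    if (n_flowers <= 0).any():
        raise StudyValidationError("n_flowers must be positive")
    if ((n_fruits < 0) | (n_fruits > n_flowers)).any():
        raise StudyValidationError("n_fruits must lie in [0, n_flowers]")
    return 100.0 * n_fruits / n_flowers


def relative_fitness(fitness: pd.DataFrame, populations: pd.Series) -> pd.DataFrame:
    """Population-relative fruit set: fruits / population mean fruits.

    Zero-fruit individuals are included in the group means.  Within each
    population the mean of ``rel_fruit_set`` over included individuals is 1.
    """
    fitness = fitness.copy()
    pops = populations.loc[fitness.index]
    means = fitness["n_fruits"].groupby(pops).transform("mean")
    if (means <= 0).any():
        bad = pops[means <= 0].iloc[0]
        raise StudyValidationError(
            f"population {bad!r} has zero mean fruit count"
        )
    fitness["rel_fruit_set"] = fitness["n_fruits"] / means
    return fitness


def z_transform(traits: pd.DataFrame) -> pd.DataFrame:
    """Standardise each column to mean 0, sample (n-1) standard deviation 1."""
    sd = traits.std(axis=0, ddof=1)
    if (~(sd > 0)).any():
        bad = sd.index[~(sd > 0)][0]
        raise StudyValidationError(f"constant trait column {bad!r} cannot be standardised")
    return (traits - traits.mean(axis=0)) / sd
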