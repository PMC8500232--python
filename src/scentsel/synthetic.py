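"""Synthetic study generator with known ground truth.

Emulates the statistical structure the analysis pipeline assumes: a
hyperdiverse, strongly zero-inflated scent matrix (hurdle model — a
per-compound detection Bernoulli times a log-normal amount), a multiplicative
regional difference in emission, population structure, optional positive
dependence between compounds through a shared log-scale latent factor, and a
planted Lande–Arnold fitness surface (linear gradients beta, quadratic
gradients gamma) read out as binomial fruit counts.

Every stochastic quantity flows through one `numpy.random.Generator` seeded
from the truth object, so a (truth, seed) pair regenerates a study exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ScentMatrix, Study, fruit_set_pct, relative_fitness


def _default_populations() -> dict[str, list[tuple[str, int]]]:
    # mirrors the two most extensively sampled field populations
    return {"north": [("JOS", 43)], "south": [("DAO", 68)]}


@dataclass
class SyntheticTruth:
    """Ground-truth parameters for a synthetic scent-selection study.

    Attributes
    ----------
    populations : mapping region -> list of (population, n_samples)
    n_compounds : number of candidate volatiles
    detection_shape : exponent k such that detection probabilities are drawn
        as U^k with U uniform; the default 1.94 puts ~70% of compounds below
        a detection rate of 0.5, matching the zero-inflation level the
        pipeline is designed for
    mu_loc, mu_scale : hyperparameters of the per-compound log-normal
        location (drawn Normal(mu_loc, mu_scale))
    sigma_range : range of per-compound log-normal scales
    region_multiplier : m >= 1, multiplicative emission excess of the south
        (the field data show a roughly 3-fold difference)
    rho : pairwise dependence level in [0, 1); induced by one shared latent
        factor on the log scale with loading sqrt(rho)
    beta, gamma : planted linear and quadratic selection gradients, mapping
        compound index -> value (standardised-trait scale)
    fitness_noise_sd : sd of the Gaussian noise on latent relative fitness
    baseline_fruiting : b in (0, 1); expected fruiting fraction at w = 1
    flowers_range : inclusive range of flowers per plant
    seed : base seed; all randomness derives from it
    """

    populations: dict[str, list[tuple[str, int]]] = field(
        default_factory=_default_populations
    )
    n_compounds: int = 90
    detection_shape: float = 1.94
    detection_probs: list[float] | None = None
    mu_loc: float = 0.5
    mu_scale: float = 1.2
    sigma_range: tuple[float, float] = (0.6, 1.2)
    region_multiplier: float = 3.0
    rho: float = 0.3
    beta: dict[int, float] = field(default_factory=dict)
    gamma: dict[int, float] = field(default_factory=dict)
    fitness_noise_sd: float = 0.5
    baseline_fruiting: float = 0.4
    flowers_range: tuple[int, int] = (30, 70)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.region_multiplier >= 1):
            raise ValueError("region_multiplier must be >= 1")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if not (0 < self.baseline_fruiting < 1):
            raise ValueError("baseline_fruiting must lie in (0, 1)")
        if self.sigma_range[0] <= 0:
            raise ValueError("log-normal scale must be positive")
        if self.detection_probs is not None:
            p = np.asarray(self.detection_probs, dtype=float)
            if len(p) != self.n_compounds:
                raise ValueError("detection_probs length must equal n_compounds")
            if ((p < 0) | (p > 1)).any():
                raise ValueError("detection probabilities must lie in [0, 1]")
        for idx in list(self.beta) + list(self.gamma):
            if not (0 <= idx < self.n_compounds):
                raise ValueError(f"planted gradient index {idx} out of range")

    # -- derived, deterministic in (truth, seed) ---------------------------

    def rng(self, stream: str = "") -> np.random.Generator:
        h = hashlib.sha256(f"{self.seed}:{stream}".encode()).digest()
        return np.random.default_rng(int.from_bytes(h[:4], "big"))

    def compound_params(self) -> pd.DataFrame:
        """Per-compound (p_c, mu_c, sigma_c), reproducible from the seed."""
        rng = self.rng("compounds")
        if self.detection_probs is not None:
            p = np.asarray(self.detection_probs, dtype=float)
            rng.uniform(size=self.n_compounds)  # keep stream alignment
        else:
            p = rng.uniform(size=self.n_compounds) ** self.detection_shape
        mu = rng.normal(self.mu_loc, self.mu_scale, size=self.n_compounds)
        sigma = rng.uniform(*self.sigma_range, size=self.n_compounds)
        ids = [f"C{i:03d}" for i in range(self.n_compounds)]
        return pd.DataFrame(
            {"p": p, "mu": mu, "sigma": sigma},
            index=pd.Index(ids, name="compound_id"),
        )

    def expected_richness(self) -> float:
        """Expected nonzero-compound count per sample, sum of p_c."""
        return float(self.compound_params()["p"].sum())

    # -- serialisation -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["beta"] = {int(k): float(v) for k, v in self.beta.items()}
        d["gamma"] = {int(k): float(v) for k, v in self.gamma.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticTruth":
        d = yaml.safe_load(Path(path).read_text())
        d["populations"] = {
            r: [(p, int(n)) for p, n in pops] for r, pops in d["populations"].items()
        }
        d["sigma_range"] = tuple(d["sigma_range"])
        d["flowers_range"] = tuple(d["flowers_range"])
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


def generate_emissions(truth: SyntheticTruth) -> tuple[ScentMatrix, pd.DataFrame]:
    """Draw the scent matrix and sample metadata.

    amount_ic = Bernoulli(p_c) * LogNormal(mu_c + log(m)*[south], sigma_c),
    with the log-scale noise split between a shared per-sample factor
    (loading sqrt(rho)) and an independent part, which induces positive
    correlation between compound amounts within a sample.
    """
    params = truth.compound_params()
    rng = truth.rng("emissions")

    rows, pops, regions = [], [], []
    for region, poplist in truth.populations.items():
        for pop, n in poplist:
            for i in range(n):
                rows.append(f"{pop}{i:03d}")
                pops.append(pop)
                regions.append(region)
    n_samples = len(rows)
    n_c = truth.n_compounds

    detected = rng.uniform(size=(n_samples, n_c)) < params["p"].to_numpy()
    shared = rng.standard_normal(size=(n_samples, 1))
    eps = rng.standard_normal(size=(n_samples, n_c))
    zlog = np.sqrt(truth.rho) * shared + np.sqrt(1 - truth.rho) * eps
    log_amount = (
        params["mu"].to_numpy()
        + np.log(truth.region_multiplier)
        * (np.asarray(regions) == "south")[:, None]
        + params["sigma"].to_numpy() * zlog
    )
    amounts = np.where(detected, np.exp(log_amount), 0.0)

    matrix = ScentMatrix(
        pd.DataFrame(amounts, index=pd.Index(rows, name="sample_id"),
                     columns=params.index.copy()),
        mode="absolute",
    )
    samples = pd.DataFrame(
        {
            "population": pops,
            "region": regions,
            "sample_type": "inflorescence",
            "year": 2018,
        },
        index=pd.Index(rows, name="sample_id"),
    )
    return matrix, samples


def _tolerant_z(values: pd.DataFrame) -> pd.DataFrame:
    """z-scores with constant (e.g. all-zero) columns mapped to zero."""
    sd = values.std(axis=0, ddof=1)
    out = values - values.mean(axis=0)
    ok = sd > 0
    out.loc[:, ok] = out.loc[:, ok] / sd[ok]
    out.loc[:, ~ok] = 0.0
    return out


def latent_fitness(matrix: ScentMatrix, truth: SyntheticTruth,
                   noise: bool = True) -> pd.Series:
    """Latent relative fitness w = 1 + sum beta_c z_c + 1/2 sum gamma_c z_c^2 + eps."""
    z = _tolerant_z(matrix.values)
    w = np.ones(matrix.n_samples)
    cols = matrix.compound_ids
    for idx, b in truth.beta.items():
        w = w + b * z[cols[idx]].to_numpy()
    for idx, g in truth.gamma.items():
        w = w + 0.5 * g * z[cols[idx]].to_numpy() ** 2
    if noise and truth.fitness_noise_sd > 0:
        rng = truth.rng("fitness")
        w = w + rng.normal(0.0, truth.fitness_noise_sd, size=matrix.n_samples)
    return pd.Series(w, index=matrix.values.index, name="latent_w")


def generate_fitness(matrix: ScentMatrix, truth: SyntheticTruth) -> pd.DataFrame:
    """Read the planted fitness surface out as binomial fruit counts.

    The fruiting fraction is clamp(b * w, 0, 1); flowers per plant are
    uniform over the configured range; fruits ~ Binomial(flowers, fraction).
    """
    bad = [i for i in list(truth.beta) + list(truth.gamma)
           if i >= matrix.n_compounds]
    if bad:
        raise ValueError(f"planted gradient index(es) {bad} exceed matrix compounds")
    w = latent_fitness(matrix, truth)
    frac = np.clip(truth.baseline_fruiting * w.to_numpy(), 0.0, 1.0)
    rng = truth.rng("fruits")
    lo, hi = truth.flowers_range
    flowers = rng.integers(lo, hi + 1, size=matrix.n_samples)
    fruits = rng.binomial(flowers, frac)
    out = pd.DataFrame(
        {"n_fruits": fruits, "n_flowers": flowers},
        index=w.index,
    )
    out["pct_fruit_set"] = fruit_set_pct(out["n_fruits"], out["n_flowers"])
    return out


def generate_study(truth: SyntheticTruth) -> tuple[Study, pd.Series]:
    """Full synthetic study plus the latent fitness used to generate it."""
    matrix, samples = generate_emissions(truth)
    fitness = generate_fitness(matrix, truth)
    fitness = relative_fitness(fitness, samples["population"])
    descriptors = pd.DataFrame(
        {
            "name": [f"UNK{1000 + i}" for i in range(truth.n_compounds)],
            "kri": [1000 + i for i in range(truth.n_compounds)],
            "compound_class": "unknown",
            "verified": False,
        },
        index=pd.Index(matrix.compound_ids, name="compound_id"),
    )
    study = Study(scent=matrix, samples=samples, descriptors=descriptors,
                  fitness=fitness)
    return study, latent_fitness(matrix, truth)


def generate_null(truth: SyntheticTruth) -> tuple[Study, pd.Series]:
    """Same study with all gradients zeroed (type-I-error harness).

    Region and population structure of the emissions is kept as configured;
    pass ``region_multiplier=1`` in the truth for a fully exchangeable null.
    """
    null_truth = SyntheticTruth(
        **{**asdict(truth), "beta": {}, "gamma": {}},
    )
    # asdict deep-copies; restore tuple-typed fields
    null_truth.populations = {
        r: [(p, int(n)) for p, n in pops]
        for r, pops in null_truth.populations.items()
    }
    return generate_study(null_truth)
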