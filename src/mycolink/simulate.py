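"""Synthetic plant x AMF-inoculum feedback experiments with known ground truth.

The generator emulates a fully crossed greenhouse design — four host
species (A-D) x five inoculation treatments (inocula A-D plus a sterilised
control) x 10 replicate pots — together with the derived amplicon OTU
tables for the trap-culture soils (5 samples per inoculum) and the
sequenced root systems (a subset of replicate pots per host x inoculum
cell).

Biomass model
-------------
Pot total biomass = baseline(host) * rho[host, inoculum] * lognormal
noise with a configurable coefficient of variation, where ``rho`` is the
multiplicative inoculation effect (rho = 1 for controls).  The true
mycorrhizal growth response is therefore ln(rho) and is recovered exactly
when the noise CV is zero.

Community model
---------------
Counts follow a Dirichlet-multinomial: each inoculum carries its own base
proportions over the OTU pool (strongly separated between inocula, as
trap cultures from different hosts are); per sample the proportions are
perturbed by a Dirichlet draw and, for configured OTU blocks, by a shared
lognormal latent factor that induces rank correlation of the configured
sign within the block.  Blocks are what the downstream co-occurrence
networks should detect: inocula with more/larger blocks yield denser
networks.  The default block layout makes network density decrease in the
order C > B > A > D while the default growth effects increase in that
order, so the headline negative complexity-growth relationship is part of
the simulated ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import HOSTS, OtuTable, validate_traits

__all__ = [
    "Block",
    "SimulationConfig",
    "GroundTruth",
    "simulate_biomass",
    "simulate_otu_table",
    "simulate_experiment",
    "DEFAULT_TRUE_MGR",
]

TREATMENTS = ("A", "B", "C", "D")  # non-control inocula

# Default log growth effects ln(rho[host, inoculum]); rows = hosts A-D,
# columns = inocula A-D.  Chosen to emulate the study system: the grass
# host D responds most, strongest with its conspecific inoculum D;
# host C responds least with its conspecific inoculum (negative feedback);
# inoculum D is the most and inoculum C the least beneficial overall.
DEFAULT_TRUE_MGR = pd.DataFrame(
    [
        [0.70, 0.65, 0.10, 0.90],
        [0.45, 0.40, 0.30, 0.75],
        [0.35, 0.45, 0.087, 0.767],
        [1.00, 0.90, 1.10, 2.057],
    ],
    index=list(HOSTS),
    columns=list(TREATMENTS),
)

_ORDERS = {
    "Glomerales": [("Glomeraceae", "Glomus"), ("Glomeraceae", "Rhizophagus"),
                   ("Claroideoglomeraceae", "Claroideoglomus"),
                   ("Glomeraceae", "Funneliformis")],
    "Diversisporales": [("Diversisporaceae", "Diversispora"),
                        ("Acaulosporaceae", "Acaulospora")],
    "Paraglomerales": [("Paraglomeraceae", "Paraglomus")],
}


@dataclass(frozen=True)
class Block:
    """A group of OTUs sharing a latent abundance factor.

    ``correlation`` in (-1, 1) sets the strength of the induced rank
    correlation; a negative sign splits the block into two anti-correlated
    halves (all-pairs negative correlation is not realisable for >2 OTUs).
    """

    size: int
    correlation: float


def _default_block_spec() -> dict[str, list[Block]]:
    return {
        "A": [Block(8, 0.95)],
        "B": [Block(10, 0.95), Block(6, 0.95)],
        "C": [Block(14, 0.95), Block(12, 0.95), Block(10, 0.95)],
        "D": [Block(6, 0.95)],
    }


@dataclass
class SimulationConfig:
    """Parameters of one simulated feedback experiment."""

    n_hosts: int = 4
    n_inocula: int = 5  # four treatments + control
    reps_biomass: int = 10
    reps_root_seq: int = 4
    n_otus: int = 165
    n_soil_samples_per_inoculum: int = 5
    library_size_range: tuple[int, int] = (3000, 40000)
    n_low_depth_samples: int = 4  # forced below the 5,000-read discard cutoff
    low_depth_cutoff: int = 5000
    rarefaction_floor: int = 5283  # retained samples are drawn at >= this depth
    effect_matrix: pd.DataFrame | None = None  # rho[host, inoculum], control = 1
    baseline_biomass: dict[str, float] = field(
        default_factory=lambda: {"A": 1.2, "B": 1.0, "C": 0.8, "D": 0.5}
    )
    biomass_cv: float = 0.3
    block_spec: dict[str, list[Block]] = field(default_factory=_default_block_spec)
    concentration: float = 150.0  # Dirichlet overdispersion (larger = less noise)
    inoculum_sd: float = 1.2  # log-sd of inoculum-specific OTU preference
    host_sd: float = 0.3  # log-sd of host-specific OTU preference (roots)
    sample_jitter_sd: float = 0.6  # log-sd of independent per-sample OTU noise
    block_boost: float = 4.0  # block OTU base mass, in units of the median OTU
    base_proportions: dict[str, np.ndarray] | None = None  # optional override
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_matrix is None:
            self.effect_matrix = np.exp(DEFAULT_TRUE_MGR)
        rho = np.asarray(self.effect_matrix, dtype=float)
        if (rho <= 0).any():
            raise ValueError("all effect-matrix entries rho must be > 0")
        if self.biomass_cv < 0:
            raise ValueError("biomass_cv must be >= 0")
        if self.reps_biomass < 2:
            raise ValueError("need at least 2 replicate pots per treatment")
        total = 0
        for inoc, blocks in self.block_spec.items():
            for b in blocks:
                if not -1 < b.correlation < 1:
                    raise ValueError(
                        f"block correlation {b.correlation} for inoculum {inoc} "
                        "outside (-1, 1)"
                    )
                total += b.size
        if total > self.n_otus:
            raise ValueError("block sizes sum exceeds n_otus")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid library_size_range")

    @property
    def hosts(self) -> list[str]:
        return list(HOSTS[: self.n_hosts])

    @property
    def inocula(self) -> list[str]:
        return list(TREATMENTS[: self.n_inocula - 1]) + ["control"]

    @property
    def treatments(self) -> list[str]:
        return list(TREATMENTS[: self.n_inocula - 1])

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named stream of the experiment."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.rng_seed, spawn_key=(stream,))
        )


_STREAM_BIOMASS, _STREAM_BASE, _STREAM_SOIL, _STREAM_ROOT = range(4)


@dataclass
class GroundTruth:
    """Exactly recomputable truth underlying one simulated experiment."""

    true_mgr: pd.DataFrame  # hosts x inocula (control column = 0)
    true_psf: pd.Series  # per host
    true_block_memberships: dict[str, list[list[str]]]
    true_library_sizes: pd.Series

    def to_json(self, path) -> None:
        payload = {
            "true_mgr": self.true_mgr.to_dict(),
            "true_psf": self.true_psf.to_dict(),
            "true_block_memberships": self.true_block_memberships,
            "true_library_sizes": {k: int(v) for k, v in self.true_library_sizes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _rho(config: SimulationConfig) -> pd.DataFrame:
    rho = pd.DataFrame(config.effect_matrix).copy()
    rho.index = config.hosts
    rho.columns = config.treatments
    rho["control"] = 1.0
    return rho


def ground_truth_mgr(config: SimulationConfig) -> pd.DataFrame:
    return np.log(_rho(config))


def ground_truth_psf(config: SimulationConfig) -> pd.Series:
    """Host-level ln(mean conspecific / mean heterospecific) implied by rho."""
    rho = _rho(config)[config.treatments]
    out = {}
    for h in config.hosts:
        if h not in rho.columns:
            continue
        hetero = [i for i in config.treatments if i != h]
        out[h] = float(np.log(rho.loc[h, h] / rho.loc[h, hetero].mean()))
    return pd.Series(out, name="true_psf")


def simulate_biomass(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the full factorial pot experiment; one row per pot."""
    rng = config.rng(_STREAM_BIOMASS)
    rho = _rho(config)
    sigma = float(np.sqrt(np.log1p(config.biomass_cv**2)))
    rows = []
    for h in config.hosts:
        for i in config.inocula:
            for r in range(1, config.reps_biomass + 1):
                mean_total = config.baseline_biomass[h] * rho.loc[h, i]
                # mean-one lognormal noise keeps E[biomass] = baseline * rho
                noise = np.exp(rng.normal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0
                total = mean_total * noise
                above_frac = float(np.clip(rng.normal(0.6, 0.04), 0.35, 0.85))
                colonization = (
                    rng.uniform(0.0, 0.03) if i == "control" else rng.beta(8, 2)
                )
                rows.append(
                    {
                        "pot_id": f"pot_{h}_{i}_{r}",
                        "host": h,
                        "inoculum": i,
                        "aboveground_biomass": total * above_frac,
                        "belowground_biomass": total * (1 - above_frac),
                        "total_biomass": total,
                        "height": 10.0 * total ** (1 / 3) * np.exp(rng.normal(0, 0.05)),
                        "colonization": colonization,
                        "n_survivors": int(rng.choice([3, 2], p=[0.9, 0.1])),
                    }
                )
    return validate_traits(pd.DataFrame(rows))


def _otu_ids(config: SimulationConfig) -> list[str]:
    return [f"OTU{k + 1:03d}" for k in range(config.n_otus)]


def _block_memberships(config: SimulationConfig) -> dict[str, list[list[str]]]:
    """Assign disjoint OTU id ranges to the configured blocks, in order."""
    ids = _otu_ids(config)
    out: dict[str, list[list[str]]] = {}
    cursor = 0
    for inoc in config.treatments:
        out[inoc] = []
        for b in config.block_spec.get(inoc, []):
            out[inoc].append(ids[cursor : cursor + b.size])
            cursor += b.size
    return out


def _base_proportions(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Inoculum-specific expected OTU proportions (shared by soil and roots)."""
    if config.base_proportions is not None:
        return {
            i: np.asarray(p, dtype=float) / np.sum(p)
            for i, p in config.base_proportions.items()
        }
    rng = config.rng(_STREAM_BASE)
    n = config.n_otus
    global_abund = np.exp(rng.normal(0.0, 0.8, size=n))  # shared species pool
    members = _block_memberships(config)
    ids = _otu_ids(config)
    index = {o: k for k, o in enumerate(ids)}
    out = {}
    for inoc in config.treatments:
        pref = np.exp(rng.normal(0.0, config.inoculum_sd, size=n))
        p = global_abund * pref
        # block OTUs are hallmark taxa of their inoculum: pin them to a
        # healthy, uniform base mass so they survive the prevalence filter
        # within their own group
        level = float(np.median(p)) * config.block_boost
        for block in members.get(inoc, []):
            for o in block:
                p[index[o]] = level
        out[inoc] = p / p.sum()
    return out


def _taxonomy(config: SimulationConfig) -> pd.DataFrame:
    rng = config.rng(_STREAM_BASE).spawn(1)[0]
    orders = list(_ORDERS)
    rows = []
    for o in _otu_ids(config):
        order = orders[int(rng.choice(len(orders), p=[0.55, 0.3, 0.15]))]
        family, genus = _ORDERS[order][int(rng.integers(len(_ORDERS[order])))]
        rows.append({"otu_id": o, "genus": genus, "family": family, "order": order})
    return pd.DataFrame(rows).set_index("otu_id")


def _block_signs(block: Block) -> np.ndarray:
    if block.correlation >= 0:
        return np.ones(block.size)
    signs = np.ones(block.size)
    signs[block.size // 2 :] = -1.0
    return signs


def _library_sizes(
    config: SimulationConfig, n_samples: int, n_low: int, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = config.library_size_range
    floor = min(max(lo, config.rarefaction_floor), hi)
    sizes = rng.integers(floor, hi + 1, size=n_samples)
    if n_low > 0 and lo < config.low_depth_cutoff:
        low_hi = min(hi, config.low_depth_cutoff - 1)
        low_idx = rng.choice(n_samples, size=min(n_low, n_samples), replace=False)
        sizes[low_idx] = rng.integers(lo, low_hi + 1, size=len(low_idx))
    return sizes


def _draw_counts(
    config: SimulationConfig,
    base: np.ndarray,
    blocks: list[Block],
    block_members: list[list[str]],
    otu_index: dict[str, int],
    library_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    p = base.copy()
    for b, members in zip(blocks, block_members):
        t = rng.normal()
        scale = 2.5 * abs(b.correlation)
        signs = _block_signs(b)
        for s, o in zip(signs, members):
            p[otu_index[o]] *= np.exp(s * scale * t)
    # independent per-OTU lognormal jitter: overdispersion beyond the
    # Dirichlet, and a guard against closure-induced spurious correlation
    if config.sample_jitter_sd > 0:
        p = p * np.exp(rng.normal(0.0, config.sample_jitter_sd, size=p.size))
    p = p / p.sum()
    alpha = config.concentration * p
    # Dirichlet-multinomial; guard against zero alpha for zero-support OTUs
    support = alpha > 0
    q = np.zeros_like(p)
    q[support] = rng.dirichlet(alpha[support])
    return rng.multinomial(library_size, q)


def simulate_otu_table(config: SimulationConfig, compartment: str) -> OtuTable:
    """Simulate the soil (trap-culture) or root amplicon OTU table."""
    if compartment not in ("soil", "root"):
        raise ValueError(f"unknown compartment {compartment!r}")
    base = _base_proportions(config)
    members = _block_memberships(config)
    otu_index = {o: k for k, o in enumerate(_otu_ids(config))}
    tax = _taxonomy(config)
    rng = config.rng(_STREAM_SOIL if compartment == "soil" else _STREAM_ROOT)

    samples: list[tuple[str, dict]] = []
    if compartment == "soil":
        for i in config.treatments:
            for r in range(1, config.n_soil_samples_per_inoculum + 1):
                samples.append(
                    (f"soil_{i}_{r}", {"host": "none", "inoculum": i, "compartment": "soil"})
                )
        n_low = config.n_low_depth_samples // 2
    else:
        for h in config.hosts:
            for i in config.treatments:
                for r in range(1, config.reps_root_seq + 1):
                    samples.append(
                        (
                            f"root_{h}_{i}_{r}",
                            {
                                "host": h,
                                "inoculum": i,
                                "compartment": "root",
                                "pot_id": f"pot_{h}_{i}_{r}",
                            },
                        )
                    )
        n_low = config.n_low_depth_samples - config.n_low_depth_samples // 2

    sizes = _library_sizes(config, len(samples), n_low, rng)
    host_pref = {
        h: np.exp(rng.normal(0.0, config.host_sd, size=config.n_otus))
        for h in config.hosts
    }
    counts = np.zeros((len(samples), config.n_otus), dtype=np.int64)
    for k, (sid, meta) in enumerate(samples):
        i = meta["inoculum"]
        p = base[i].copy()
        if compartment == "root":
            p = p * host_pref[meta["host"]]
            p = p / p.sum()
        counts[k] = _draw_counts(
            config,
            p,
            config.block_spec.get(i, []),
            members.get(i, []),
            otu_index,
            int(sizes[k]),
            rng,
        )
    counts_df = pd.DataFrame(
        counts, index=[s for s, _ in samples], columns=_otu_ids(config)
    )
    meta_df = pd.DataFrame([m for _, m in samples], index=[s for s, _ in samples])
    meta_df.index.name = "sample_id"
    return OtuTable(counts_df, meta_df, tax)


def simulate_experiment(
    config: SimulationConfig | None = None,
) -> tuple[OtuTable, OtuTable, pd.DataFrame, GroundTruth]:
    """Simulate soil table, root table, trait table, and the ground truth."""
    config = config or SimulationConfig()
    soil = simulate_otu_table(config, "soil")
    root = simulate_otu_table(config, "root")
    traits = simulate_biomass(config)
    sizes = pd.concat([soil.library_sizes, root.library_sizes])
    truth = GroundTruth(
        true_mgr=ground_truth_mgr(config),
        true_psf=ground_truth_psf(config),
        true_block_memberships=_block_memberships(config),
        true_library_sizes=sizes,
    )
    return soil, root, traits, truth
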