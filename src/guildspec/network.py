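"""Guild-structured species x resource networks and their ground truth.

A community of N species is organized into k guilds: groups of species
with similar resource preferences.  Each guild prefers one block of the
shared resources.  The binary adjacency g_ia (does species i consume
resource a?) is Bernoulli with probability ``p_in`` inside the preferred
block and ``p_out`` outside; with two guilds these are parameterized by a
single bias q via p_in = 0.5 + q, p_out = 0.5 - q.  On top of the shared
blocks every species owns one private resource nobody else consumes,
which prevents extinction in the dynamics.

The gain matrix G_ia = r_ia * gamma_ia (uptake rate times yield) defines
the ground-truth resource-utilization overlap GG^T whose off-diagonal
entries quantify pairwise competition; its block structure is what the
inference half of the package tries to recover from time series.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._rng import substream

__all__ = [
    "GuildConfig",
    "ResourceNetwork",
    "finite_size_rates",
    "heterogeneous_sizes",
    "sample_network",
    "expected_no_link_prob",
    "expected_degree",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class GuildConfig:
    """Parameters of the random guild-structured consumer-resource network.

    ``guild_bias`` (q) is the two-guild shorthand: when given, p_in and
    p_out default to 0.5 + q and 0.5 - q.  For scaled systems pass
    explicit ``p_in``/``p_out`` (see :func:`finite_size_rates`).
    ``q_n``/``q_m`` set geometric heterogeneity of guild sizes and
    per-guild shared-resource counts (1.0 = homogeneous).
    """

    n_species: int = 6
    n_resources: int = 30
    n_guilds: int = 2
    guild_bias: float | None = None
    p_in: float | None = None
    p_out: float | None = None
    uptake_rate: float = 0.1
    yield_mean: float = 1.0
    yield_sd: float = 1.0 / 6.0
    q_n: float = 1.0
    q_m: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_resources < 1 or self.n_guilds < 1:
            raise ValueError("n_species, n_resources, n_guilds must be positive")
        if self.n_guilds > self.n_species:
            raise ValueError("cannot have more guilds than species")
        if self.n_resources < self.n_species:
            raise ValueError(
                "need n_resources >= n_species (one private resource per species)"
            )
        if self.guild_bias is not None:
            q = self.guild_bias
            if not 0.0 <= q <= 0.5:
                raise ValueError(f"guild_bias must lie in [0, 0.5], got {q}")
            if self.p_in is None:
                object.__setattr__(self, "p_in", 0.5 + q)
            if self.p_out is None:
                object.__setattr__(self, "p_out", 0.5 - q)
        if self.p_in is None or self.p_out is None:
            raise ValueError("provide guild_bias or explicit p_in and p_out")
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError(
                f"require 0 <= p_out <= p_in <= 1, got p_in={self.p_in}, p_out={self.p_out}"
            )
        if self.uptake_rate <= 0 or self.yield_mean <= 0 or self.yield_sd < 0:
            raise ValueError("uptake_rate, yield_mean must be positive; yield_sd >= 0")
        if self.q_n <= 0 or self.q_m <= 0:
            raise ValueError("q_n and q_m must be positive")

    @property
    def n_shared_resources(self) -> int:
        """Shared (non-private) resource count: M - N."""
        return self.n_resources - self.n_species

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "n_resources": self.n_resources,
            "n_guilds": self.n_guilds,
            "guild_bias": self.guild_bias,
            "p_in": self.p_in,
            "p_out": self.p_out,
            "uptake_rate": self.uptake_rate,
            "yield_mean": self.yield_mean,
            "yield_sd": self.yield_sd,
            "q_n": self.q_n,
            "q_m": self.q_m,
            "seed": self.seed,
        }


@dataclass
class ResourceNetwork:
    """One realization of the consumer-resource network.

    ``overlap`` is gain @ gain.T, the ground truth for link and guild
    inference; ``guild_labels`` the ground-truth guild id per species.
    ``private_resource_index[i]`` is the column of species i's private
    resource (-1 when the network was built without private resources).
    """

    adjacency: np.ndarray
    uptake: np.ndarray
    yields: np.ndarray
    gain: np.ndarray
    overlap: np.ndarray
    guild_labels: np.ndarray
    private_resource_index: np.ndarray
    config: GuildConfig | None = None

    @property
    def n_species(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_resources(self) -> int:
        return self.adjacency.shape[1]

    @classmethod
    def from_adjacency(
        cls,
        adjacency: np.ndarray,
        uptake_rate: float = 0.1,
        yields: np.ndarray | None = None,
        guild_labels: np.ndarray | None = None,
    ) -> "ResourceNetwork":
        """Build a network from an explicit binary adjacency matrix.

        Useful for hand-constructed systems (single species, no species at
        all, deterministic block patterns).
        """
        g = np.asarray(adjacency, dtype=float)
        if g.ndim != 2:
            raise ValueError("adjacency must be 2-D (n_species x n_resources)")
        if yields is None:
            yields = np.ones_like(g)
        yields = np.asarray(yields, dtype=float)
        if yields.shape != g.shape:
            raise ValueError("yields must match adjacency shape")
        if np.any(yields < 0):
            raise ValueError("yields must be non-negative")
        uptake = uptake_rate * g
        gain = uptake * yields
        n = g.shape[0]
        if guild_labels is None:
            guild_labels = np.zeros(n, dtype=int)
        return cls(
            adjacency=g,
            uptake=uptake,
            yields=yields,
            gain=gain,
            overlap=gain @ gain.T,
            guild_labels=np.asarray(guild_labels, dtype=int),
            private_resource_index=np.full(n, -1, dtype=int),
            config=None,
        )


def finite_size_rates(n_species: int, guild_bias: float) -> tuple[float, float]:
    """Block-connection probabilities scaled so mean degree stays finite.

    p_in = (1/2 + q) (N/6)^(-1/2) and p_out = (1/2 - q) (N/6)^(-1); at
    N = 6 these reduce to the unscaled 0.5 +/- q parameterization.
    """
    if n_species < 6:
        raise ValueError("scaling is anchored at N = 6; need n_species >= 6")
    if not 0.0 <= guild_bias <= 0.5:
        raise ValueError("guild_bias must lie in [0, 0.5]")
    ratio = n_species / 6.0
    p_in = (0.5 + guild_bias) * ratio ** (-0.5)
    p_out = (0.5 - guild_bias) / ratio
    if not (0.0 <= p_out <= 1.0 and 0.0 <= p_in <= 1.0):
        raise ValueError(f"scaled probabilities out of range: p_in={p_in}, p_out={p_out}")
    return p_in, p_out


def _round_geometric(total: int, k: int, ratio: float, minimum: int) -> np.ndarray:
    """Geometric series summing to ``total`` after ceil-rounding corrections.

    Sizes follow n_j = ratio**j * n_0 rounded up; an overall deficit is
    added to the largest part; an excess is removed from the smallest part
    that still has more than ``minimum`` members, preferring the smallest.
    """
    if k < 1:
        raise ValueError("need at least one part")
    if total < minimum * k:
        raise ValueError(f"cannot split {total} into {k} parts of at least {minimum}")
    weights = ratio ** np.arange(k)
    first = total / weights.sum()
    sizes = np.array([math.ceil(first * w) for w in weights], dtype=int)
    sizes = np.maximum(sizes, minimum)
    while sizes.sum() < total:
        sizes[np.argmax(sizes)] += 1
    while sizes.sum() > total:
        order = np.argsort(sizes, kind="stable")  # smallest first
        for idx in order:
            if sizes[idx] > minimum:
                sizes[idx] -= 1
                break
        else:  # pragma: no cover - guarded by the feasibility check above
            raise ValueError("rounding could not satisfy the minimum part size")
    return sizes


def heterogeneous_sizes(
    n_species: int,
    n_resources: int,
    n_guilds: int,
    q_n: float = 1.0,
    q_m: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Guild sizes and per-guild shared-resource counts.

    Guild sizes N_j = q_n**j N_0 (rounded up, corrected to sum to N, with
    a minimum guild size of 2); shared-resource counts M_j = q_m**j M_0
    with sum M_j + N = M (each species keeps one private resource).
    """
    if n_species < 2 * n_guilds:
        raise ValueError(
            f"infeasible: {n_guilds} guilds of >= 2 species need N >= {2 * n_guilds}"
        )
    m_shared = n_resources - n_species
    if m_shared < n_guilds:
        raise ValueError("need at least one shared resource per guild")
    guild_sizes = _round_geometric(n_species, n_guilds, q_n, minimum=2)
    resource_counts = _round_geometric(m_shared, n_guilds, q_m, minimum=1)
    return guild_sizes, resource_counts


def sample_network(config: GuildConfig) -> ResourceNetwork:
    """Draw one random guild-structured network.

    Shared-resource adjacency entries are Bernoulli(p_in) inside the
    species' preferred block and Bernoulli(p_out) elsewhere; yields are
    Gaussian(yield_mean, yield_sd) redrawn until non-negative.  The
    adjacency and yield draws use independent named substreams of
    ``config.seed``.
    """
    n, m, k = config.n_species, config.n_resources, config.n_guilds
    guild_sizes, resource_counts = heterogeneous_sizes(n, m, k, config.q_n, config.q_m)
    m_shared = config.n_shared_resources

    guild_labels = np.repeat(np.arange(k), guild_sizes)
    resource_block = np.repeat(np.arange(k), resource_counts)

    rng_adj = substream(config.seed, "adjacency")
    probs = np.where(
        guild_labels[:, None] == resource_block[None, :], config.p_in, config.p_out
    )
    g = np.zeros((n, m))
    g[:, :m_shared] = (rng_adj.random((n, m_shared)) < probs).astype(float)
    private_index = m_shared + np.arange(n)
    g[np.arange(n), private_index] = 1.0

    rng_yield = substream(config.seed, "yields")
    yields = rng_yield.normal(config.yield_mean, config.yield_sd, size=(n, m))
    # redraw negatives until the whole matrix is non-negative
    neg = yields < 0
    while np.any(neg):
        yields[neg] = rng_yield.normal(config.yield_mean, config.yield_sd, size=int(neg.sum()))
        neg = yields < 0

    uptake = config.uptake_rate * g
    gain = uptake * yields
    return ResourceNetwork(
        adjacency=g,
        uptake=uptake,
        yields=yields,
        gain=gain,
        overlap=gain @ gain.T,
        guild_labels=guild_labels,
        private_resource_index=private_index,
        config=config,
    )


def expected_no_link_prob(
    p_in: float,
    p_out: float,
    n_shared_resources: int,
    n_guilds: int,
    same_guild: bool,
) -> float:
    """Probability that two species share no resource (zero overlap).

    ``n_shared_resources`` counts the shared resources entering the block
    construction; private resources cannot create overlap and are excluded.
    """
    m, k = n_shared_resources, n_guilds
    if same_guild:
        return (1 - p_in**2) ** (m / k) * (1 - p_out**2) ** (m * (1 - 1 / k))
    return (1 - p_in * p_out) ** (2 * m / k) * (1 - p_out**2) ** (m * (1 - 2 / k))


def expected_degree(
    p_in: float,
    p_out: float,
    n_species: int,
    n_shared_resources: int,
    n_guilds: int,
) -> float:
    """Expected number of species a focal species shares a resource with."""
    n, k = n_species, n_guilds
    p_same = expected_no_link_prob(p_in, p_out, n_shared_resources, k, same_guild=True)
    p_diff = expected_no_link_prob(p_in, p_out, n_shared_resources, k, same_guild=False)
    return (1 - p_same) * (n / k - 1) + (1 - p_diff) * n * (1 - 1 / k)


def _write_matrix(path: Path, values: np.ndarray, row_ids, col_ids) -> None:
    import pandas as pd

    pd.DataFrame(values, index=row_ids, columns=col_ids).to_csv(path, sep="\t")


def save_network(network: ResourceNetwork, outdir: str | Path) -> None:
    """Write adjacency/gain/overlap TSVs plus a JSON sidecar with config/labels."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species = [f"sp{i}" for i in range(network.n_species)]
    resources = [f"res{a}" for a in range(network.n_resources)]
    _write_matrix(outdir / "adjacency.tsv", network.adjacency, species, resources)
    _write_matrix(outdir / "gain.tsv", network.gain, species, resources)
    _write_matrix(outdir / "overlap.tsv", network.overlap, species, species)
    sidecar = {
        "config": network.config.to_dict() if network.config is not None else None,
        "guild_labels": network.guild_labels.tolist(),
        "private_resource_index": network.private_resource_index.tolist(),
    }
    (outdir / "network.json").write_text(json.dumps(sidecar, indent=2))


def load_network(outdir: str | Path) -> ResourceNetwork:
    """Inverse of :func:`save_network` (yields are recovered from gain/uptake)."""
    import pandas as pd

    outdir = Path(outdir)
    adjacency = pd.read_csv(outdir / "adjacency.tsv", sep="\t", index_col=0).to_numpy()
    gain = pd.read_csv(outdir / "gain.tsv", sep="\t", index_col=0).to_numpy()
    overlap = pd.read_csv(outdir / "overlap.tsv", sep="\t", index_col=0).to_numpy()
    sidecar = json.loads((outdir / "network.json").read_text())
    config = GuildConfig(**sidecar["config"]) if sidecar["config"] else None
    uptake_rate = config.uptake_rate if config else 0.1
    uptake = uptake_rate * adjacency
    with np.errstate(divide="ignore", invalid="ignore"):
        yields = np.where(uptake > 0, gain / np.where(uptake > 0, uptake, 1.0), 0.0)
    if not np.allclose(gain @ gain.T, overlap, rtol=1e-8, atol=1e-10):
        warnings.warn("stored overlap is inconsistent with gain @ gain.T")
    return ResourceNetwork(
        adjacency=adjacency,
        uptake=uptake,
        yields=yields,
        gain=gain,
        overlap=overlap,
        guild_labels=np.asarray(sidecar["guild_labels"], dtype=int),
        private_resource_index=np.asarray(sidecar["private_resource_index"], dtype=int),
        config=config,
    )
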