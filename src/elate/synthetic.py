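"""Synthetic rep-seq repertoires with the structure the analyses assume.

Generated CDR3s mimic real beta-chain junctions, which are not strings of
independent letters but mosaics of germline-templated and random segments.
Each clone is assembled as

    CAS + V-extension + N1 + D-fragment + N2 + J-suffix

where the ``CAS`` prefix and a small V-derived extension come from the V
gene, the D fragment is drawn from a catalogue of short glycine-rich
germline fragments (with truncations), N1/N2 are junctional insertions of
0-4 random residues from a biased amino-acid usage, and the suffix is one of
the amino-acid endings of the human TRBJ segments (all terminating in F).
Total lengths are rejection-sampled into the configured range, giving a
unimodal distribution peaking near 13-14 residues.

Clone sizes follow a discrete power law (heavy tail), V genes are drawn from
a rank-biased catalogue, samples belonging to one "host" share clones from a
host-specific public pool, and specificity classes are defined by a
consensus core motif copied with a per-position mutation rate.

The junctional insertions keep near-duplicate CDR3s across samples rare:
pairwise edit distances between unrelated clones concentrate well above 2,
as observed in real repertoires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from elate.io_encoding import AA_ALPHABET, RepertoireSample, TCRClone, write_repertoire

#: Amino-acid usage inside the CDR3 core; biased toward the glycine/serine
#: rich composition of junctional regions.  Order follows AA_ALPHABET.
DEFAULT_AA_FREQS: tuple[float, ...] = (
    0.055,  # A
    0.010,  # C
    0.045,  # D
    0.060,  # E
    0.040,  # F
    0.110,  # G
    0.025,  # H
    0.035,  # I
    0.025,  # K
    0.070,  # L
    0.015,  # M
    0.045,  # N
    0.050,  # P
    0.055,  # Q
    0.070,  # R
    0.110,  # S
    0.065,  # T
    0.045,  # V
    0.015,  # W
    0.055,  # Y
)

PREFIX = "CAS"
SUFFIX = "F"

#: Amino-acid endings of the human TRBJ segments (all end in the conserved F).
J_SUFFIXES: tuple[str, ...] = (
    "NTEAFF",
    "NYGYTF",
    "GNTIYF",
    "NEKLFF",
    "NQPQHF",
    "NSPLHF",
    "YNEQFF",
    "TGELFF",
    "SDTQYF",
    "KNIQYF",
    "QETQYF",
    "ANVLTF",
    "SYEQYF",
)

#: Short germline D-segment fragments (glycine-rich, with truncations).
D_FRAGMENTS: tuple[str, ...] = (
    "G",
    "GG",
    "GGG",
    "TGG",
    "GTGG",
    "LAG",
    "GLA",
    "SGG",
    "TAG",
    "QG",
    "GQ",
    "RG",
    "GR",
    "DR",
    "TG",
)

#: Short V-derived extensions following the conserved CAS.
V_EXTENSIONS: tuple[str, ...] = ("", "S", "R", "T", "SL", "SQ", "RD", "SD")


@dataclass
class GeneratorConfig:
    """Knobs of the repertoire generator.

    ``n_samples`` samples are split evenly over ``n_hosts`` host groups; each
    host owns a public pool of ``public_pool_size`` clones and every sample
    of that host carries each pool clone independently with probability
    ``sharing_probability``.  ``length_range`` bounds the total CDR3 length
    (prefix and suffix included); lengths follow a binomial bump across the
    range, peaking mid-range.  ``clone_size_exponent`` is the power-law tail
    exponent alpha of the clone-size law P(s) ~ s^-alpha.  ``motif_classes``
    maps class names to (consensus core, mutation rate) pairs for
    specificity-group generation.
    """

    n_samples: int = 4
    clones_per_sample: int = 1000
    n_hosts: int = 2
    length_range: tuple[int, int] = (8, 18)
    aa_frequencies: tuple[float, ...] = DEFAULT_AA_FREQS
    n_v_genes: int = 30
    clone_size_exponent: float = 2.5
    public_pool_size: int = 100
    sharing_probability: float = 0.5
    motif_classes: dict[str, tuple[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < len(PREFIX) + len(SUFFIX) + 1 or hi < lo:
            raise ValueError("length_range infeasible for the conserved termini")
        if self.clone_size_exponent <= 1:
            raise ValueError("clone_size_exponent must exceed 1")
        if abs(sum(self.aa_frequencies) - 1.0) > 1e-6 or len(self.aa_frequencies) != 20:
            raise ValueError("aa_frequencies must be a normalized 20-vector")
        for name, (core, rate) in self.motif_classes.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"motif class {name}: mutation rate must be in [0,1]")
            if lo - len(PREFIX) - len(SUFFIX) < len(core) and hi - len(PREFIX) - len(SUFFIX) < len(core):
                raise ValueError(f"motif class {name}: consensus core longer than any core length")
        if self.n_samples % self.n_hosts:
            raise ValueError("n_samples must be divisible by n_hosts")


def _random_core(rng: np.random.Generator, core_len: int, freqs: np.ndarray) -> str:
    idx = rng.choice(20, size=core_len, p=freqs)
    return "".join(AA_ALPHABET[i] for i in idx)


def _mutate(core: str, rate: float, rng: np.random.Generator, freqs: np.ndarray) -> str:
    out = []
    for ch in core:
        if rng.random() < rate:
            out.append(AA_ALPHABET[rng.choice(20, p=freqs)])
        else:
            out.append(ch)
    return "".join(out)


def _draw_clone_size(rng: np.random.Generator, alpha: float) -> int:
    """Discrete Pareto: P(size >= s) = s^-(alpha-1)."""
    u = rng.random()
    return int(np.floor(u ** (-1.0 / (alpha - 1.0))))


class _CloneFactory:
    def __init__(self, config: GeneratorConfig, rng: np.random.Generator) -> None:
        self.config = config
        self.rng = rng
        self.freqs = np.asarray(config.aa_frequencies)
        ranks = np.arange(1, config.n_v_genes + 1, dtype=float)
        self.v_probs = (1.0 / ranks) / (1.0 / ranks).sum()
        self.v_names = [f"TRBV{i}" for i in range(1, config.n_v_genes + 1)]

    def new_cdr3(self, consensus: str | None = None, mutation_rate: float = 0.0) -> str:
        if consensus is not None:
            return PREFIX + _mutate(consensus, mutation_rate, self.rng, self.freqs) + SUFFIX
        lo, hi = self.config.length_range
        rng = self.rng
        while True:
            vext = V_EXTENSIONS[rng.integers(len(V_EXTENSIONS))]
            n1 = _random_core(rng, int(rng.integers(0, 5)), self.freqs)
            d = D_FRAGMENTS[rng.integers(len(D_FRAGMENTS))]
            n2 = _random_core(rng, int(rng.integers(0, 5)), self.freqs)
            j = J_SUFFIXES[rng.integers(len(J_SUFFIXES))][int(rng.integers(0, 3)) :]
            cdr3 = PREFIX + vext + n1 + d + n2 + j
            if lo <= len(cdr3) <= hi:
                return cdr3

    def new_clone(self, consensus: str | None = None, mutation_rate: float = 0.0) -> TCRClone:
        return TCRClone(
            cdr3=self.new_cdr3(consensus, mutation_rate),
            v_gene=self.v_names[self.rng.choice(self.config.n_v_genes, p=self.v_probs)],
            frequency=float(_draw_clone_size(self.rng, self.config.clone_size_exponent)),
        )


def generate_repertoire(config: GeneratorConfig) -> list[RepertoireSample]:
    """Generate ``n_samples`` samples grouped into host categories.

    Each host group gets a private public-clone pool; pools are kept disjoint
    across hosts so zero sharing probability guarantees no clone crosses host
    boundaries.  Sample categories are the host names (``host0``, ...).
    """
    rng = np.random.default_rng(config.seed)
    factory = _CloneFactory(config, rng)
    per_host = config.n_samples // config.n_hosts

    pools: list[list[TCRClone]] = []
    seen: set[str] = set()
    for _ in range(config.n_hosts):
        pool = []
        while len(pool) < config.public_pool_size:
            clone = factory.new_clone()
            if clone.cdr3 in seen:
                continue  # keep host pools disjoint
            seen.add(clone.cdr3)
            pool.append(clone)
        pools.append(pool)

    samples: list[RepertoireSample] = []
    for host in range(config.n_hosts):
        for rep in range(per_host):
            clones: list[TCRClone] = []
            for pool_clone in pools[host]:
                if rng.random() < config.sharing_probability:
                    clones.append(pool_clone)
            while len(clones) < config.clones_per_sample:
                clone = factory.new_clone()
                if clone.cdr3 in seen:
                    continue  # private clones never collide with any pool
                clones.append(clone)
            samples.append(
                RepertoireSample(
                    sample_id=f"host{host}_s{rep}",
                    clones=clones[: config.clones_per_sample],
                    category=f"host{host}",
                )
            )
    return samples


def generate_labeled_classes(config: GeneratorConfig) -> list[RepertoireSample]:
    """One sample per motif class, cores derived from the class consensus.

    Class separability is controlled by the mutation rate: at 0 every core
    equals the consensus; at 1 every position is redrawn from the background
    usage, making classes statistically indistinguishable.
    """
    if len(config.motif_classes) < 2:
        raise ValueError("need at least 2 motif classes")
    rates = {rate for _, rate in config.motif_classes.values()}
    cores = [core for core, _ in config.motif_classes.values()]
    if len(set(cores)) < len(cores) and rates == {0.0}:
        import warnings

        warnings.warn("identical consensus cores with zero mutation rate: labels are degenerate")
    rng = np.random.default_rng(config.seed)
    factory = _CloneFactory(config, rng)
    samples = []
    for name, (core, rate) in config.motif_classes.items():
        clones = [factory.new_clone(consensus=core, mutation_rate=rate) for _ in range(config.clones_per_sample)]
        samples.append(RepertoireSample(sample_id=name, clones=clones, category=name))
    return samples


def write_samples(samples: list[RepertoireSample], out_dir: str | Path, config: GeneratorConfig | None = None) -> None:
    """Write per-sample TSVs plus a ground-truth JSON into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth: dict = {"samples": {}}
    if config is not None:
        truth["config"] = asdict(config)
    for sample in samples:
        write_repertoire(sample, out_dir / f"{sample.sample_id}.tsv")
        truth["samples"][sample.sample_id] = {
            "category": sample.category,
            "n_clones": len(sample),
        }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
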