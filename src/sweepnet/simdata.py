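"""Simulation inputs: msms command construction, ms-format I/O, synthetic fixtures.

Training data for sweep detection comes from coalescent simulations in the
text format of Hudson's ``ms`` and its descendants (msms, msprime's
``mspms``).  This module builds the simulator command line for a given
parameterization, parses/writes ms-format replicates, and provides a
self-contained fixture generator that emulates the haplotype structure of a
selective sweep (one common haplotype surrounded by rarer ones) so that the
rest of the pipeline can be exercised without an external simulator.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np

__all__ = [
    "SimulationParams",
    "HaplotypeAlignment",
    "MsParseError",
    "build_simulator_command",
    "parse_ms",
    "write_ms",
    "generate_fixture",
    "generate_fixtures",
    "three_epoch_demography",
    "one_epoch_demography",
]


def one_epoch_demography() -> list[tuple[float, float]]:
    """Constant-size population (no size changes)."""
    return []


def three_epoch_demography() -> list[tuple[float, float]]:
    """Example 3-epoch history for a European-like population.

    A bottleneck followed by regrowth: times are in generations before
    present, sizes relative to the reference Ne.  These values are an
    illustrative placeholder, not an estimate for any particular population;
    supply your own epochs for real analyses.
    """
    return [(2000.0, 0.2), (3500.0, 1.0)]


@dataclass(frozen=True)
class SimulationParams:
    """Parameterization of a single-population sweep simulation.

    Attributes
    ----------
    sample_size : int
        Number of sampled haplotypes (chromosomes), n.
    region_length : int
        Simulated region length in base pairs, L.
    mutation_rate : float
        Per-base per-generation mutation rate, mu.
    recombination_rate : float
        Per-base per-generation recombination rate, r.
    reference_ne : float
        Diploid effective population size used for scaling, Ne.
    selection_coefficient : float
        Selection coefficient S in 2*Ne units; 0 means neutrality.
    selection_onset_years : float
        Age of the selection onset in years before present.
    generation_time : float
        Years per generation, used to convert the onset to coalescent time.
    initial_allele_frequency : float
        Population frequency of the beneficial allele at onset.
    demography : sequence of (time, size)
        Epoch changes as (time in generations before present, size relative
        to reference_ne), strictly increasing in time.
    n_replicates : int
        Number of independent replicates to simulate.
    seed : int
        Simulator random seed.
    """

    sample_size: int = 128
    region_length: int = 80_000
    mutation_rate: float = 1.5e-8
    recombination_rate: float = 1.0e-8
    reference_ne: float = 10_000.0
    selection_coefficient: float = 0.0
    selection_onset_years: float = 15_000.0
    generation_time: float = 25.0
    initial_allele_frequency: float = 0.01
    demography: Sequence[tuple[float, float]] = field(default_factory=tuple)
    n_replicates: int = 1
    seed: int = 1

    def __post_init__(self) -> None:
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2")
        for name in ("mutation_rate", "recombination_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.reference_ne <= 0:
            raise ValueError("reference_ne must be > 0")
        if self.selection_coefficient < 0:
            raise ValueError("selection_coefficient must be >= 0")
        if not 0 < self.initial_allele_frequency < 1:
            raise ValueError("initial_allele_frequency must be in (0, 1)")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        times = [t for t, _ in self.demography]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("demography times must be strictly increasing")
        if any(s <= 0 for _, s in self.demography):
            raise ValueError("demography relative sizes must be > 0")

    @property
    def theta(self) -> float:
        """Population-scaled mutation rate, 4*Ne*mu*L."""
        return 4.0 * self.reference_ne * self.mutation_rate * self.region_length

    @property
    def rho(self) -> float:
        """Population-scaled recombination rate, 4*Ne*r*L."""
        return 4.0 * self.reference_ne * self.recombination_rate * self.region_length

    @property
    def selection_onset_coalescent(self) -> float:
        """Onset time in coalescent units of 4*Ne generations."""
        generations = self.selection_onset_years / self.generation_time
        return generations / (4.0 * self.reference_ne)


@dataclass
class HaplotypeAlignment:
    """One simulation replicate: binary haplotype matrix plus positions.

    ``matrix`` has one row per haplotype and one column per segregating
    site; ``positions`` are the sites' relative coordinates in [0, 1].
    """

    matrix: np.ndarray
    positions: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional")
        if self.matrix.shape[1] != self.positions.shape[0]:
            raise ValueError("column count must equal number of positions")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def validate(self) -> None:
        """Check invariants: binary entries, sorted positions, segregating columns."""
        if self.n_sites == 0:
            return
        vals = np.unique(self.matrix)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("matrix entries must be 0 or 1")
        if np.any(self.positions < 0) or np.any(self.positions > 1):
            raise ValueError("positions must lie in [0, 1]")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be non-decreasing")
        counts = self.matrix.sum(axis=0)
        if np.any(counts == 0) or np.any(counts == self.n_haplotypes):
            raise ValueError("every column must be segregating")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeAlignment):
            return NotImplemented
        return (
            self.matrix.shape == other.matrix.shape
            and np.array_equal(self.matrix, other.matrix)
            and np.allclose(self.positions, other.positions)
        )


def build_simulator_command(params: SimulationParams) -> str:
    """Assemble the msms command line for ``params``.

    The command encodes the scaled mutation (theta = 4*Ne*mu*L) and
    recombination (rho = 4*Ne*r*L) parameters, epoch size changes as ``-eN``
    flags in units of 4*Ne generations, and — when ``selection_coefficient``
    is positive — semidominant selection (``-SAA S -SAa S/2``), the onset
    time and starting allele frequency (``-SI``), and a selected site at the
    region midpoint (``-Sp 0.5``).  The string is deterministic for fixed
    parameters.  The command is *not* executed here; feed its output file to
    :func:`parse_ms`.
    """
    p = params
    parts = [
        "msms",
        "-N", _fmt(p.reference_ne),
        "-ms", str(p.sample_size), str(p.n_replicates),
        "-t", _fmt(p.theta),
        "-r", _fmt(p.rho), str(p.region_length),
    ]
    for time_gen, rel_size in p.demography:
        t_coal = time_gen / (4.0 * p.reference_ne)
        parts += ["-eN", _fmt(t_coal), _fmt(rel_size)]
    if p.selection_coefficient > 0:
        s = p.selection_coefficient
        parts += [
            "-SAA", _fmt(s),
            "-SAa", _fmt(s / 2.0),
            "-Sp", "0.5",
            "-SI", _fmt(p.selection_onset_coalescent), "1",
            _fmt(p.initial_allele_frequency),
            "-Smark",
        ]
    parts += ["-seed", str(p.seed)]
    return " ".join(parts)


def _fmt(x: float) -> str:
    """Render a float without trailing zeros but keeping at least one decimal."""
    x = round(float(x), 10)  # absorb binary round-off in scaled parameters
    if x == int(x):
        return f"{x:.1f}"
    return repr(x)


class MsParseError(ValueError):
    """Raised when ms-format text violates the format conventions."""


def parse_ms(stream: TextIO | str) -> list[HaplotypeAlignment]:
    """Parse ms/msms-format text into a list of alignments.

    Replicates are delimited by ``//`` lines followed by ``segsites: k``,
    ``positions: p1 ... pk`` and one haplotype row of k characters per
    sample.  Command-echo and seed lines are ignored.  Multi-allelic
    characters (anything outside ``{0,1}``) are rejected: this pipeline is
    strictly diallelic.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.rstrip("\n") for ln in stream]
    alignments: list[HaplotypeAlignment] = []
    i = 0
    rep = 0
    while i < len(lines):
        if lines[i].strip() != "//":
            i += 1
            continue
        rep += 1
        i += 1
        # skip blank lines between the delimiter and segsites
        while i < len(lines) and not lines[i].strip():
            i += 1
        if i >= len(lines) or not lines[i].startswith("segsites:"):
            raise MsParseError(f"replicate {rep}: expected 'segsites:' line")
        try:
            segsites = int(lines[i].split(":", 1)[1])
        except ValueError as exc:
            raise MsParseError(f"replicate {rep}: bad segsites line") from exc
        i += 1
        if segsites == 0:
            alignments.append(
                HaplotypeAlignment(
                    np.zeros((0, 0), dtype=np.int8),
                    np.zeros(0),
                    provenance={"replicate": rep},
                )
            )
            continue
        if i >= len(lines) or not lines[i].startswith("positions:"):
            raise MsParseError(f"replicate {rep}: expected 'positions:' line")
        positions = np.array([float(x) for x in lines[i].split()[1:]])
        if positions.size != segsites:
            raise MsParseError(
                f"replicate {rep}: {positions.size} positions but segsites={segsites}"
            )
        i += 1
        rows: list[list[int]] = []
        while i < len(lines) and lines[i].strip() and lines[i].strip() != "//":
            row = lines[i].strip()
            if len(row) != segsites:
                raise MsParseError(
                    f"replicate {rep}: haplotype row of length {len(row)}, "
                    f"expected {segsites}"
                )
            if set(row) - {"0", "1"}:
                raise MsParseError(
                    f"replicate {rep}: non-binary characters in haplotype row "
                    "(multi-allelic ms output is not supported)"
                )
            rows.append([int(c) for c in row])
            i += 1
        if not rows:
            raise MsParseError(f"replicate {rep}: no haplotype rows")
        alignments.append(
            HaplotypeAlignment(
                np.array(rows, dtype=np.int8),
                positions,
                provenance={"replicate": rep},
            )
        )
    return alignments


def write_ms(
    alignments: Iterable[HaplotypeAlignment],
    stream: TextIO,
    header: str = "sweepnet fixtures",
) -> None:
    """Write alignments as ms-dialect text that :func:`parse_ms` inverts."""
    stream.write(header + "\n\n")
    for aln in alignments:
        stream.write("//\n")
        stream.write(f"segsites: {aln.n_sites}\n")
        if aln.n_sites == 0:
            stream.write("\n")
            continue
        pos = " ".join(f"{p:.8f}" for p in aln.positions)
        stream.write(f"positions: {pos}\n")
        for row in aln.matrix:
            stream.write("".join("1" if v else "0" for v in row) + "\n")
        stream.write("\n")


def _neutral_column(n: int, rng: np.random.Generator) -> np.ndarray:
    """One neutral column: derived count i ~ 1/i (standard neutral SFS)."""
    i = np.arange(1, n)
    p = (1.0 / i) / np.sum(1.0 / i)
    k = rng.choice(i, p=p)
    col = np.zeros(n, dtype=np.int8)
    col[rng.choice(n, size=k, replace=False)] = 1
    return col


def generate_fixture(
    n: int,
    target_sites: int,
    sweep_intensity: float = 0.0,
    core_width: float = 0.3,
    rng_seed: int | np.random.Generator = 0,
) -> HaplotypeAlignment:
    """Generate a synthetic haplotype alignment with an optional sweep core.

    Neutral columns draw their derived-allele count from the standard
    neutral site-frequency spectrum, P(i) proportional to 1/i, with carriers
    placed uniformly at random.  When ``sweep_intensity`` > 0, a central
    ``core_width`` fraction of columns carries the sweep signature: a fixed
    set of ``round(sweep_intensity * n)`` rows (capped at n-1 so columns
    stay segregating) shares one identical haplotype pattern, while the
    remaining rows carry neutral draws.  This mimics the common extended
    haplotype a selective sweep produces.  Positions are sorted uniforms on
    [0, 1].  Deterministic for a fixed seed.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if target_sites < 2:
        raise ValueError("target_sites must be >= 2")
    if not 0.0 <= sweep_intensity <= 1.0:
        raise ValueError("sweep_intensity must be in [0, 1]")
    if not 0.0 <= core_width <= 1.0:
        raise ValueError("core_width must be in [0, 1]")

    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    matrix = np.zeros((n, target_sites), dtype=np.int8)

    core_cols: set[int] = set()
    carriers = np.zeros(0, dtype=np.intp)
    if sweep_intensity > 0 and core_width > 0:
        n_core = max(1, int(round(core_width * target_sites)))
        start = (target_sites - n_core) // 2
        core_cols = set(range(start, start + n_core))
        n_carriers = min(int(round(sweep_intensity * n)), n - 1)
        n_carriers = max(n_carriers, 1)
        carriers = rng.choice(n, size=n_carriers, replace=False)

    non_carriers = np.setdiff1d(np.arange(n), carriers)
    for j in range(target_sites):
        if j in core_cols:
            # carriers all share one haplotype pattern (a fair coin per core
            # column: swept haplotypes carry ancestral as well as derived
            # alleles); the remaining rows get a neutral sub-column, which
            # keeps the full column segregating whichever allele is shared
            shared = int(rng.integers(0, 2))
            col = np.full(n, shared, dtype=np.int8)
            if non_carriers.size >= 2:
                col[non_carriers] = _neutral_column(non_carriers.size, rng)
            else:
                col[non_carriers] = 1 - shared
            matrix[:, j] = col
        else:
            matrix[:, j] = _neutral_column(n, rng)

    positions = np.sort(rng.uniform(0.0, 1.0, size=target_sites))
    aln = HaplotypeAlignment(
        matrix,
        positions,
        provenance={
            "source": "fixture",
            "n": n,
            "target_sites": target_sites,
            "sweep_intensity": sweep_intensity,
            "core_width": core_width,
        },
    )
    aln.validate()
    return aln


def generate_fixtures(
    n_replicates: int,
    n: int,
    target_sites: int,
    sweep_intensity: float = 0.0,
    core_width: float = 0.3,
    rng_seed: int = 0,
) -> list[HaplotypeAlignment]:
    """Generate ``n_replicates`` independent fixtures from one seeded stream."""
    rng = np.random.default_rng(rng_seed)
    out = []
    for rep in range(n_replicates):
        aln = generate_fixture(n, target_sites, sweep_intensity, core_width, rng)
        aln.provenance["replicate"] = rep
        aln.provenance["seed"] = rng_seed
        out.append(aln)
    return out
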