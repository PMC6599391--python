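"""Synthetic FACS-seq screen generator.

Emulates the sort-seq experiment end to end: per-cell fluorescence is
lognormal (Normal in log2 space) around a construct- and state-specific true
median; an infected population (default 15% infection, single integration per
cell) is gated into five bins -- negative, low, high, top 5-10%, top 5% --
where the negative gate comes from an uninfected control sample and the
positive gates from the quantiles of the fluorescence-positive population;
sequencing of each sorted bin is multinomial over the constructs occupying
that bin at a fixed per-sample read depth (~1e6 reads/sample by default,
>=100 cells per construct). Technical replicates re-sample sequencing only;
biological replicates additionally perturb the true medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .library_design import ASCI_SITE, FLANK_3, LibraryReference

BIN_NAMES = ("negative", "low", "high", "top5to10", "top5")

# Study-condition defaults, fixed once: lognormal cell-to-cell spread of 0.8
# log2 units, ~15% infectivity, >=100 cells per library member, ~1e6 reads
# per sequenced sample, and a 99.5th-percentile negative gate on the
# uninfected control.
DEFAULT_SIGMA = 0.8            # log2 a.u., cell-to-cell spread
DEFAULT_INFECTION_RATE = 0.15
DEFAULT_CELLS_PER_CONSTRUCT = 100
DEFAULT_DEPTH = 1_000_000      # reads per (state, replicate, bin) sample
DEFAULT_NEGATIVE_QUANTILE = 0.995
DEFAULT_BASELINE_LOG2 = 7.0    # autofluorescence median, log2 a.u.
DEFAULT_BIO_SD = 1.0           # biological-replicate perturbation, log2 units
READ_LENGTH = 150


class GateError(ValueError):
    """Raised when a fluorescence sample cannot support the five-bin gating."""


@dataclass(frozen=True)
class BinScheme:
    """The five-gate fluorescence partition.

    ``edges`` are 6 increasing breakpoints defining half-open intervals
    [edges[b], edges[b+1]) on the linear fluorescence axis; ``means`` holds
    the mean fluorescence of cells inside each gate (ybar_b), strictly
    increasing across the ordered bins.
    """

    edges: np.ndarray   # shape (6,)
    means: np.ndarray   # shape (5,), ybar_b per bin

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        means = np.asarray(self.means, dtype=float)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "means", means)
        if edges.shape != (6,) or means.shape != (5,):
            raise GateError("need 6 edges and 5 bin means")
        if not np.all(np.diff(edges) > 0):
            raise GateError("bin edges must be strictly increasing")
        if not np.all(np.diff(means) > 0):
            raise GateError("per-bin mean fluorescence must be strictly increasing")

    @property
    def names(self) -> tuple[str, ...]:
        return BIN_NAMES

    def assign(self, fluorescence: np.ndarray) -> np.ndarray:
        """Bin index (0..4) for each linear-scale fluorescence value."""
        idx = np.searchsorted(self.edges[1:-1], fluorescence, side="right")
        return idx


@dataclass
class GroundTruth:
    """True per-construct, per-state activity underlying a simulated screen.

    ``medians`` is a DataFrame (construct x state) of median log2
    fluorescence; ``sigma`` the cell-to-cell spread (log2 units); ``bio_sd``
    the scale of the additive Normal perturbation applied to medians in each
    biological replicate.
    """

    medians: pd.DataFrame
    sigma: float = DEFAULT_SIGMA
    bio_sd: float = DEFAULT_BIO_SD
    specific_constructs: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not np.isfinite(self.medians.to_numpy()).all():
            raise ValueError("ground-truth medians must be finite")

    @property
    def states(self) -> list[str]:
        return list(self.medians.columns)

    @property
    def construct_ids(self) -> list[str]:
        return list(self.medians.index)


def make_ground_truth(
    construct_ids: Sequence[str],
    states: Sequence[str] = ("A", "B"),
    seed: int = 0,
    frac_active: float = 0.6,
    active_range: tuple[float, float] = (8.0, 16.0),
    baseline_log2: float = DEFAULT_BASELINE_LOG2,
    state_jitter_sd: float = 0.8,
    n_specific: dict[str, int] | None = None,
    specific_range: tuple[float, float] = (12.0, 15.0),
    sigma: float = DEFAULT_SIGMA,
    bio_sd: float = DEFAULT_BIO_SD,
) -> GroundTruth:
    """Draw a ground truth with shared baseline activity plus planted specifics.

    A fraction ``frac_active`` of constructs is active with a base log2
    activity uniform on ``active_range``, perturbed per state by
    Normal(0, state_jitter_sd) so activities correlate across states;
    inactive constructs sit at the autofluorescence baseline.
    ``n_specific[state]`` constructs are planted as specific to that state:
    active (uniform on ``specific_range``) there and at baseline elsewhere.
    """
    if len(states) < 2:
        raise ValueError("need at least two states")
    rng = np.random.default_rng(seed)
    ids = list(construct_ids)
    n = len(ids)
    n_specific = dict(n_specific or {})
    total_specific = sum(n_specific.values())
    if total_specific > n:
        raise ValueError("more planted specifics than constructs")

    medians = np.full((n, len(states)), baseline_log2, dtype=float)
    active = rng.random(n) < frac_active
    base = rng.uniform(*active_range, size=n)
    for j in range(len(states)):
        jitter = rng.normal(0.0, state_jitter_sd, size=n)
        medians[active, j] = base[active] + jitter[active]

    # Planted state-specific constructs overwrite the correlated background.
    order = rng.permutation(n)
    cursor = 0
    specific: dict[str, list[str]] = {}
    for state, count in n_specific.items():
        if state not in states:
            raise ValueError(f"unknown state {state!r}")
        picked = order[cursor:cursor + count]
        cursor += count
        j = list(states).index(state)
        medians[picked, :] = baseline_log2
        medians[picked, j] = rng.uniform(*specific_range, size=len(picked))
        specific[state] = [ids[i] for i in picked]

    df = pd.DataFrame(medians, index=pd.Index(ids, name="construct_id"),
                      columns=list(states))
    return GroundTruth(df, sigma=sigma, bio_sd=bio_sd, specific_constructs=specific)


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------

def derive_gates(
    positive_fluor: np.ndarray,
    control_fluor: np.ndarray,
    negative_quantile: float = DEFAULT_NEGATIVE_QUANTILE,
) -> BinScheme:
    """Derive the five-bin gate scheme from cytometry samples.

    The negative gate is the ``negative_quantile`` of the uninfected control.
    Fluorescence-positive cells (above that gate) are split into top 5%
    (>95th percentile), top 5-10% (90th-95th), and the remaining 90% halved
    at their median into low/high. ``ybar_b`` is the mean fluorescence of the
    library sample's cells inside each gate.
    """
    positive_fluor = np.asarray(positive_fluor, dtype=float)
    control_fluor = np.asarray(control_fluor, dtype=float)
    if positive_fluor.size == 0 or control_fluor.size == 0:
        raise GateError("empty fluorescence sample")

    neg_gate = float(np.quantile(control_fluor, negative_quantile))
    # strictly above the gate: cells exactly at the control quantile are not
    # fluorescence-positive
    positives = positive_fluor[positive_fluor > neg_gate]
    if positives.size < 20:
        raise GateError(
            f"only {positives.size} fluorescence-positive cells; "
            "need >= 20 for 5% quantile gates"
        )
    q90, q95 = np.quantile(positives, [0.90, 0.95])
    lower90 = positives[positives < q90]
    if lower90.size == 0:
        raise GateError("no cells below the 90th percentile gate")
    mid = float(np.median(lower90))

    edges = np.array([-np.inf, neg_gate, mid, q90, q95, np.inf])
    if not np.all(np.diff(edges) > 0):
        raise GateError("degenerate gates: duplicate cut points")

    idx = np.searchsorted(edges[1:-1], positive_fluor, side="right")
    ctrl_idx = np.searchsorted(edges[1:-1], control_fluor, side="right")
    means = np.empty(5)
    for b in range(5):
        cells = positive_fluor[idx == b]
        if cells.size == 0:
            # fall back to the control sample (e.g. an all-positive library
            # sample leaves the negative gate empty)
            cells = control_fluor[ctrl_idx == b]
        if cells.size == 0:
            raise GateError("a gate contains no cells; cannot estimate bin means")
        means[b] = cells.mean()
    return BinScheme(edges=edges, means=means)


# ---------------------------------------------------------------------------
# Screen simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedScreen:
    """A simulated sort-seq screen: counts, gates, truth, provenance.

    ``counts`` is construct x samples with MultiIndex columns
    (state, replicate, bin); replicate ids encode biological and technical
    structure as ``b<i>t<j>``. Per-sample counts sum exactly to ``depth``
    (multinomial conservation) whenever the sample's bins are occupied.
    """

    counts: pd.DataFrame
    bin_schemes: dict[str, BinScheme]
    truth: GroundTruth
    seed: int
    depth: int
    sample_sheet: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for state, rep, bin_name in self.counts.columns:
            rows.append({
                "sample_id": f"{state}_{rep}_{bin_name}",
                "state": state,
                "replicate": rep,
                "replicate_type": "technical" if not rep.endswith("t1") else "biological",
                "bin": bin_name,
            })
        self.sample_sheet = pd.DataFrame(rows).set_index("sample_id")

    def flat_counts(self) -> pd.DataFrame:
        """Counts with flat string sample columns ``state_replicate_bin``."""
        flat = self.counts.copy()
        flat.columns = [f"{s}_{r}_{b}" for s, r, b in flat.columns]
        return flat

    def to_tsv(self, path: str | Path) -> None:
        self.flat_counts().to_csv(path, sep="\t")


def simulate_screen(
    truth: GroundTruth,
    depth: int = DEFAULT_DEPTH,
    cells_per_construct: int = DEFAULT_CELLS_PER_CONSTRUCT,
    infection_rate: float = DEFAULT_INFECTION_RATE,
    n_bio: int = 2,
    n_tech: int = 2,
    seed: int = 0,
    baseline_log2: float = DEFAULT_BASELINE_LOG2,
) -> SimulatedScreen:
    """Simulate the FACS-binned sequencing screen for every state in ``truth``.

    Per state: gates are derived once from a simulated infected population
    (infected cells mixed with uninfected cells per ``infection_rate``) and an
    uninfected control. Per biological replicate the true medians are
    perturbed by Normal(0, bio_sd); each construct contributes
    ``cells_per_construct`` infected cells whose fluorescence is
    2**Normal(median, sigma) and which are assigned to bins by the gates.
    Each technical replicate then draws sequencing counts as a multinomial
    over (construct, bin) occupancy at ``depth`` reads per sorted-bin sample.
    """
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    if cells_per_construct < 1:
        raise ValueError("cells_per_construct must be >= 1")
    rng = np.random.default_rng(seed)
    ids = truth.construct_ids
    n = len(ids)
    sigma = truth.sigma

    blocks: dict[tuple[str, str, str], np.ndarray] = {}
    bin_schemes: dict[str, BinScheme] = {}

    for state in truth.states:
        medians = truth.medians[state].to_numpy()

        # Gate derivation: the library-infected population (~infection_rate
        # infected) vs. an uninfected control, both at coverage scale.
        infected = 2.0 ** rng.normal(
            np.repeat(medians, cells_per_construct), sigma)
        n_uninfected = int(round(n * cells_per_construct
                                 * (1 - infection_rate) / infection_rate))
        uninfected = 2.0 ** rng.normal(baseline_log2, sigma, size=n_uninfected)
        control = 2.0 ** rng.normal(baseline_log2, sigma,
                                    size=max(n_uninfected, 10_000))
        population = np.concatenate([infected, uninfected])
        scheme = derive_gates(population, control)
        bin_schemes[state] = scheme

        for b in range(n_bio):
            rep_medians = medians + rng.normal(0.0, truth.bio_sd, size=n)
            cell_fluor = 2.0 ** rng.normal(
                np.repeat(rep_medians, cells_per_construct), sigma)
            cell_bins = scheme.assign(cell_fluor)
            cell_construct = np.repeat(np.arange(n), cells_per_construct)
            # occupancy[i, bin] = infected cells of construct i sorted into bin
            occupancy = np.zeros((n, 5), dtype=np.int64)
            np.add.at(occupancy, (cell_construct, cell_bins), 1)

            for t in range(n_tech):
                rep = f"b{b + 1}t{t + 1}"
                for bin_idx, bin_name in enumerate(BIN_NAMES):
                    occ = occupancy[:, bin_idx]
                    total = occ.sum()
                    if total == 0:
                        sample = np.zeros(n, dtype=np.int64)
                    else:
                        sample = rng.multinomial(depth, occ / total)
                    blocks[(state, rep, bin_name)] = sample

    columns = pd.MultiIndex.from_tuples(blocks.keys(),
                                        names=["state", "replicate", "bin"])
    counts = pd.DataFrame(np.column_stack(list(blocks.values())),
                          index=pd.Index(ids, name="construct_id"),
                          columns=columns)
    return SimulatedScreen(counts=counts, bin_schemes=bin_schemes,
                           truth=truth, seed=seed, depth=depth)


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

def _random_non_asci(rng: np.random.Generator, length: int) -> str:
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if ASCI_SITE not in seq:
            return seq


def emit_reads(
    screen: SimulatedScreen,
    library: LibraryReference,
    out_dir: str | Path,
    error_rate: float = 0.0,
    junk_fraction: float = 0.0,
    seed: int = 0,
    read_length: int = READ_LENGTH,
) -> list[Path]:
    """Write one FASTQ per sample: one read per sequencing count.

    Each read is the construct's variable region followed by the 3' flank
    (containing the AscI site), truncated to ``read_length``, with
    independent per-base substitution errors at ``error_rate``. Each read is
    replaced with probability ``junk_fraction`` by a random AscI-free
    sequence (library-independent junk). Quality is constant Phred+33 'I'.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    id_to_read = {}
    for c in library.constructs:
        id_to_read[c.construct_id] = (c.variable_region + FLANK_3)[:read_length]

    missing = set(screen.counts.index) - set(id_to_read)
    if missing:
        raise KeyError(f"constructs absent from library: {sorted(missing)[:5]}")

    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    paths: list[Path] = []
    for col in screen.counts.columns:
        state, rep, bin_name = col
        sample_id = f"{state}_{rep}_{bin_name}"
        counts = screen.counts[col]
        path = out_dir / f"{sample_id}.fastq"
        with open(path, "w") as fh:
            read_no = 0
            for construct_id, count in counts.items():
                if count == 0:
                    continue
                template = id_to_read[construct_id]
                arr = np.frombuffer(template.encode(), dtype=np.uint8)
                reads = np.tile(arr, (count, 1))
                if error_rate > 0:
                    errs = rng.random(reads.shape) < error_rate
                    # substitution: shift 1-3 letters within ACGT
                    lut = np.full(256, -1, dtype=np.int8)
                    for i, b in enumerate(bases):
                        lut[b] = i
                    shifts = rng.integers(1, 4, size=int(errs.sum()))
                    flat = reads[errs]
                    reads[errs] = bases[(lut[flat] + shifts) % 4]
                qual = "I" * reads.shape[1]
                seqs = reads.view(f"S{reads.shape[1]}").ravel()
                junk = (rng.random(count) < junk_fraction) if junk_fraction > 0 else None
                for i, s in enumerate(seqs):
                    read_no += 1
                    if junk is not None and junk[i]:
                        seq = _random_non_asci(rng, len(template))
                        fh.write(f"@{sample_id}:{read_no}\n{seq}\n+\n{'I' * len(seq)}\n")
                    else:
                        fh.write(f"@{sample_id}:{read_no}\n{s.decode()}\n+\n{qual}\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Calibration events (per-promoter cytometry)
# ---------------------------------------------------------------------------

def simulate_calibration_events(
    truth: GroundTruth,
    construct_ids: Sequence[str],
    n_events: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell fluorescence event tables for single-promoter infections.

    Returns a long DataFrame (construct_id, state, fluorescence) with
    ``n_events`` lognormal events per construct per state, emulating the
    cytometry measurements used to calibrate the activity model.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for state in truth.states:
        for cid in construct_ids:
            med = truth.medians.at[cid, state]
            fluor = 2.0 ** rng.normal(med, truth.sigma, size=n_events)
            frames.append(pd.DataFrame({
                "construct_id": cid, "state": state, "fluorescence": fluor,
            }))
    return pd.concat(frames, ignore_index=True)
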