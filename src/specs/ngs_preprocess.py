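"""Read-level and count-level preprocessing of the binned sequencing screen.

Raw reads are kept only if they contain the AscI recognition sequence
(GGCGCGCC) introduced at the 3' junction during library construction, and are
trimmed at its 5' edge so only the variable promoter sequence remains.
Trimmed reads are collapsed to unique sequences, assigned to the single
best-matching library variable region within a mismatch budget, and counted
per construct. Counts are normalized by median-of-ratios size factors and
constructs are retained only when observed in at least two replicates of
every cell state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .library_design import ASCI_SITE, LibraryReference

PSEUDOCOUNT = 1.0  # added before log2 so zero counts stay defined


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTQ filtering / trimming
# ---------------------------------------------------------------------------

def _iter_fastq(path: str | Path):
    """Yield (header, sequence) from a 4-line FASTQ, validating structure."""
    with open(path) as fh:
        record = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            record += 1
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise PreprocessError(f"{path}: malformed FASTQ record {record}")
            if len(qual) != len(seq):
                raise PreprocessError(
                    f"{path}: record {record}: quality/sequence length mismatch")
            yield header[1:].strip(), seq


def filter_and_trim(reads: str | Path | Iterable[str]) -> tuple[Counter, dict]:
    """Keep reads containing the AscI site; trim at its 5' edge.

    ``reads`` is a FASTQ path or an iterable of sequences. Returns the
    multiset of retained variable-region sequences and a QC report with
    kept/dropped totals.
    """
    if isinstance(reads, (str, Path)):
        seqs = (seq for _, seq in _iter_fastq(reads))
    else:
        seqs = iter(reads)
    kept: Counter = Counter()
    dropped = 0
    for seq in seqs:
        pos = seq.find(ASCI_SITE)
        if pos < 0:
            dropped += 1
            continue
        kept[seq[:pos]] += 1
    report = {"kept": sum(kept.values()), "dropped": dropped,
              "unique": len(kept)}
    return kept, report


# ---------------------------------------------------------------------------
# Collapse + reference matching
# ---------------------------------------------------------------------------

def _hamming_assign(seq: str, refs_by_len: Mapping[int, tuple[list[str], np.ndarray]],
                    max_mismatches: int) -> str | None:
    """Best substitution-only match among equal-length references, ties -> None."""
    entry = refs_by_len.get(len(seq))
    if entry is None:
        return None
    ids, ref_arr = entry
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    dists = (ref_arr != arr).sum(axis=1)
    best = dists.min()
    if best > max_mismatches:
        return None
    hits = np.flatnonzero(dists == best)
    if hits.size != 1:
        return None  # ambiguous best hit
    return ids[hits[0]]


def _edit_assign(seq: str, library: LibraryReference, max_mismatches: int) -> str | None:
    import edlib

    best, best_id, ambiguous = None, None, False
    for region, cid in library.index.items():
        d = edlib.align(seq, region, mode="NW", task="distance",
                        k=max_mismatches)["editDistance"]
        if d < 0:
            continue
        if best is None or d < best:
            best, best_id, ambiguous = d, cid, False
        elif d == best:
            ambiguous = True
    if best is None or ambiguous:
        return None
    return best_id


def collapse_and_count(
    trimmed: Counter | Iterable[str],
    library: LibraryReference,
    max_mismatches: int = 2,
    mode: str = "hamming",
) -> tuple[pd.Series, dict]:
    """Collapse identical sequences, assign each unique to its best reference.

    Each unique trimmed sequence is assigned to the single closest library
    variable region within ``max_mismatches`` (substitutions by default;
    ``mode='edit'`` uses edit distance via edlib, admitting indels);
    ambiguous best hits (>= 2 references at the minimal distance) stay
    unassigned. Returns per-construct raw counts (indexed by construct_id,
    zero-filled) and a report with assigned/unassigned totals.
    """
    if len(library) == 0:
        raise PreprocessError("empty library reference")
    if not isinstance(trimmed, Counter):
        trimmed = Counter(trimmed)

    # group references by length for the vectorized Hamming scan
    refs_by_len: dict[int, tuple[list[str], np.ndarray]] = {}
    if mode == "hamming":
        by_len: dict[int, tuple[list[str], list[str]]] = {}
        for region, cid in library.index.items():
            ids, regs = by_len.setdefault(len(region), ([], []))
            ids.append(cid)
            regs.append(region)
        for length, (ids, regs) in by_len.items():
            arr = np.frombuffer("".join(regs).encode(), dtype=np.uint8)
            refs_by_len[length] = (ids, arr.reshape(len(regs), length))
    elif mode != "edit":
        raise ValueError(f"unknown matching mode {mode!r}")

    counts: Counter = Counter()
    unassigned = 0
    exact = library.index
    for seq, mult in trimmed.items():
        cid = exact.get(seq)
        if cid is None:
            if mode == "hamming":
                cid = _hamming_assign(seq, refs_by_len, max_mismatches)
            else:
                cid = _edit_assign(seq, library, max_mismatches)
        if cid is None:
            unassigned += mult
        else:
            counts[cid] += mult
    series = pd.Series(
        {c.construct_id: counts.get(c.construct_id, 0) for c in library.constructs},
        name="count", dtype=np.int64)
    series.index.name = "construct_id"
    report = {"assigned": int(series.sum()), "unassigned": unassigned}
    return series, report


def count_samples(
    fastq_paths: Mapping[str, str | Path],
    library: LibraryReference,
    max_mismatches: int = 2,
    mode: str = "hamming",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run filter/trim + collapse/count per sample; return counts and QC."""
    columns = {}
    qc_rows = []
    for sample_id, path in fastq_paths.items():
        trimmed, qc = filter_and_trim(path)
        cts, match_report = collapse_and_count(trimmed, library,
                                               max_mismatches, mode)
        columns[sample_id] = cts
        qc_rows.append({"sample_id": sample_id, **qc, **match_report})
    counts = pd.DataFrame(columns)
    counts.index.name = "construct_id"
    return counts, pd.DataFrame(qc_rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Normalization (median-of-ratios size factors)
# ---------------------------------------------------------------------------

def size_factors(raw: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    The reference is the per-construct geometric mean across samples,
    computed over constructs with nonzero counts in every sample; the factor
    of sample j is the median over those constructs of count_ij / reference_i.
    A ``pseudocount`` can rescue datasets with no all-nonzero construct.
    """
    mat = raw.to_numpy(dtype=float) + pseudocount
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise PreprocessError(
            "no construct has nonzero counts in every sample; "
            "pass pseudocount > 0 to proceed")
    sub = mat[all_nonzero]
    log_ref = np.log(sub).mean(axis=1)  # log geometric mean per construct
    ratios = np.log(sub) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=raw.columns, name="size_factor")


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw and normalized screen counts plus sample metadata.

    ``raw`` is construct x sample; ``samples`` maps sample_id to
    (state, replicate, bin); ``normalized`` is raw divided by the per-sample
    median-of-ratios size factor. A provenance log records each processing
    step applied.
    """

    raw: pd.DataFrame
    samples: pd.DataFrame  # index sample_id; columns state, replicate, bin
    factors: pd.Series | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(self.raw.columns) - set(self.samples.index)
        if missing:
            raise PreprocessError(f"samples sheet missing entries: {sorted(missing)[:5]}")
        for col in ("state", "replicate", "bin"):
            if col not in self.samples.columns:
                raise PreprocessError(f"samples sheet lacks column {col!r}")

    @classmethod
    def from_screen(cls, screen) -> "CountMatrix":
        """Build directly from a SimulatedScreen (bypassing FASTQ emission)."""
        return cls(raw=screen.flat_counts(), samples=screen.sample_sheet.copy(),
                   log=["from_screen"])

    @property
    def states(self) -> list[str]:
        return sorted(self.samples["state"].unique())

    @property
    def bins(self) -> list[str]:
        return list(dict.fromkeys(self.samples["bin"]))

    def normalize(self, pseudocount: float = 0.0) -> "CountMatrix":
        self.factors = size_factors(self.raw, pseudocount=pseudocount)
        self.log.append("normalize: median-of-ratios size factors")
        return self

    @property
    def normalized(self) -> pd.DataFrame:
        if self.factors is None:
            raise PreprocessError("call .normalize() before using normalized counts")
        return self.raw.div(self.factors, axis=1)

    def replicate_filter(self, min_replicates: int = 2) -> tuple["CountMatrix", dict]:
        """Retain constructs observed in >= min_replicates replicates of every state.

        A construct counts as observed in a replicate when any bin of that
        replicate has a nonzero raw count. States with fewer than
        ``min_replicates`` replicates make the filter impossible and raise.
        """
        keep = pd.Series(True, index=self.raw.index)
        for state, sheet in self.samples.groupby("state"):
            reps = sheet["replicate"].unique()
            if len(reps) < min_replicates:
                raise PreprocessError(
                    f"state {state!r} has {len(reps)} replicate(s); "
                    f"need >= {min_replicates}")
            seen = pd.DataFrame(0, index=self.raw.index,
                                columns=list(reps), dtype=bool)
            for rep, rep_sheet in sheet.groupby("replicate"):
                cols = rep_sheet.index
                seen[rep] = (self.raw[cols] > 0).any(axis=1)
            keep &= seen.sum(axis=1) >= min_replicates
        filtered = CountMatrix(
            raw=self.raw.loc[keep].copy(),
            samples=self.samples.copy(),
            factors=self.factors,
            log=self.log + [f"replicate_filter: retained {int(keep.sum())} "
                            f"of {len(keep)} constructs"],
        )
        report = {"retained": int(keep.sum()), "dropped": int((~keep).sum())}
        return filtered, report

    def mean_normalized_by_bin(self, state: str) -> pd.DataFrame:
        """Normalized counts averaged over replicates: construct x bin."""
        sheet = self.samples[self.samples["state"] == state]
        norm = self.normalized
        cols = {}
        for bin_name, bin_sheet in sheet.groupby("bin", sort=False):
            cols[bin_name] = norm[bin_sheet.index].mean(axis=1)
        return pd.DataFrame(cols)[self.bins]

    # ---- serialization ----------------------------------------------------

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.raw.to_csv(counts_path, sep="\t")
        self.samples.to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        raw = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(raw=raw, samples=samples, log=[f"loaded {counts_path}"])


# ---------------------------------------------------------------------------
# Sanger clone identification
# ---------------------------------------------------------------------------

def match_sanger(
    clone_seq: str,
    library: LibraryReference,
    max_edits: int = 10,
) -> dict:
    """Identify a Sanger-sequenced clone against the library reference.

    Aligns every library variable region as an infix of the clone sequence
    (local/glocal alignment via edlib). An exact full-length hit is
    ``intact``; a best hit within ``max_edits`` is ``mutated`` (with the
    aligned CIGAR string); anything farther is ``unidentifiable``.
    """
    import edlib

    clone_seq = clone_seq.strip().upper()
    if not clone_seq:
        raise ValueError("empty clone sequence")
    best = None
    for region, cid in library.index.items():
        res = edlib.align(region, clone_seq, mode="HW", task="path")
        d = res["editDistance"]
        if best is None or d < best[0]:
            best = (d, cid, res["cigar"])
    d, cid, cigar = best
    if d == 0:
        return {"status": "intact", "construct_id": cid, "edits": 0, "cigar": cigar}
    if d <= max_edits:
        return {"status": "mutated", "construct_id": cid, "edits": int(d),
                "cigar": cigar}
    return {"status": "unidentifiable", "construct_id": None, "edits": int(d),
            "cigar": None}
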