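"""Heme-binding-motif scanning and comparative-genomics screens.

The heme c attachment site of c-type cytochromes is the CXXCH motif: two
cysteines that form thioether bonds to the heme vinyl groups and a histidine
axial ligand, separated by two arbitrary residues.  Proteins carrying two or
more such motifs are multiheme c-type cytochromes (MHCs), the canonical
conduits of extracellular electron transfer.  Besides the primary CxxCH
pattern this module scans the variant attachment motifs CxxxCH, CxxxxCH,
CxxCK, AxxCH and FxxCH.

Also provided: draft-assembly summary statistics (contig count, total length,
GC, N50) and a presence/absence screen of extracellular-electron-transfer
gene panels against a proteome via local protein alignment (BLOSUM62,
affine gaps, Karlin-Altschul e-values) or an external blastp.
"""

from __future__ import annotations

import dataclasses
import math
import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MotifPattern",
    "PATTERNS",
    "PRIMARY_PATTERN",
    "MotifHit",
    "scan_motifs",
    "classify_protein",
    "ProteinHemeProfile",
    "proteome_mhc_survey",
    "SurveyResult",
    "AssemblyStats",
    "assembly_stats",
    "PanelResult",
    "panel_presence",
    "read_fasta",
]

#: 20 standard residues.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity/nonstandard codes allowed in input; they match wildcard
#: positions only, never anchors.
AMBIGUOUS_AA = "XBZU"
_ALLOWED = set(STANDARD_AA) | set(AMBIGUOUS_AA) | {"*"}


@dataclasses.dataclass(frozen=True)
class MotifPattern:
    """A heme-attachment motif: fixed anchor residues with wildcard gaps."""

    name: str
    tier: str  # "primary" | "variant"

    @property
    def length(self) -> int:
        return len(self.name)

    @property
    def anchors(self) -> tuple[tuple[int, str], ...]:
        return tuple((i, c) for i, c in enumerate(self.name) if c != "x")

    def matches_at(self, seq: str, start: int) -> bool:
        if start + self.length > len(seq):
            return False
        for offset, residue in enumerate(self.name):
            c = seq[start + offset]
            if residue == "x":
                if c == "*":
                    return False
            elif c != residue:
                return False
        return True


#: Patterns in most-canonical-first precedence order used to resolve
#: cross-pattern overlaps in combined greedy counting.
PATTERNS: tuple[MotifPattern, ...] = (
    MotifPattern("CxxCH", "primary"),
    MotifPattern("CxxxCH", "variant"),
    MotifPattern("CxxxxCH", "variant"),
    MotifPattern("CxxCK", "variant"),
    MotifPattern("AxxCH", "variant"),
    MotifPattern("FxxCH", "variant"),
)
PRIMARY_PATTERN = PATTERNS[0]
_BY_NAME = {p.name: p for p in PATTERNS}


def get_pattern(name: str) -> MotifPattern:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown motif pattern {name!r}; known: {sorted(_BY_NAME)}") from None


@dataclasses.dataclass(frozen=True)
class MotifHit:
    pattern: str
    start: int  # 1-based, inclusive
    matched: str


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    for i, c in enumerate(seq):
        if c not in _ALLOWED:
            raise ValueError(f"illegal residue {c!r} at position {i + 1}")
    return seq


def scan_motifs(
    sequence: str,
    patterns: Sequence[MotifPattern] | None = None,
    overlap_policy: str = "non_overlapping_greedy",
) -> list[MotifHit]:
    """Scan a protein sequence for heme-attachment motifs.

    Under ``non_overlapping_greedy`` (default: one cysteine cannot ligate two
    hemes) each residue is used by at most one hit; patterns claim residues
    in the precedence order they are listed (most canonical first), each
    pattern scanning left to right.  Under ``all_positions`` every matching
    start position of every pattern is reported.  A stop character ``*``
    terminates the segment: no motif spans it.  Positions are 1-based.
    """
    if patterns is None:
        patterns = PATTERNS
    if overlap_policy not in ("non_overlapping_greedy", "all_positions"):
        raise ValueError(f"unknown overlap policy {overlap_policy!r}")
    seq = _validate_sequence(sequence)
    hits: list[MotifHit] = []
    if not seq:
        return hits
    if overlap_policy == "all_positions":
        for pat in patterns:
            for i in range(len(seq) - pat.length + 1):
                if pat.matches_at(seq, i):
                    hits.append(MotifHit(pat.name, i + 1, seq[i : i + pat.length]))
    else:
        occupied = np.zeros(len(seq), dtype=bool)
        for pat in patterns:
            i = 0
            while i <= len(seq) - pat.length:
                if not occupied[i : i + pat.length].any() and pat.matches_at(seq, i):
                    hits.append(MotifHit(pat.name, i + 1, seq[i : i + pat.length]))
                    occupied[i : i + pat.length] = True
                    i += pat.length
                else:
                    i += 1
    hits.sort(key=lambda h: (h.start, h.pattern))
    return hits


def classify_protein(count: int) -> str:
    """Heme-count classification: none / monoheme / multiheme / multiheme_high.

    Two or more attachment motifs define a multiheme cytochrome; six or more
    mark the high-heme class typical of dedicated iron-reducer conduits.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if count == 0:
        return "none"
    if count == 1:
        return "monoheme"
    if count < 6:
        return "multiheme"
    return "multiheme_high"


@dataclasses.dataclass(frozen=True)
class ProteinHemeProfile:
    protein_id: str
    length: int
    hits: tuple[MotifHit, ...]
    count_primary: int
    count_by_pattern: Mapping[str, int]
    classification: str

    @property
    def count_total(self) -> int:
        return len(self.hits)


@dataclasses.dataclass(frozen=True)
class SurveyResult:
    profiles: tuple[ProteinHemeProfile, ...]
    tier: str

    @property
    def n_proteins(self) -> int:
        return len(self.profiles)

    @property
    def n_multiheme(self) -> int:
        return sum(p.classification in ("multiheme", "multiheme_high") for p in self.profiles)

    @property
    def n_multiheme_high(self) -> int:
        return sum(p.classification == "multiheme_high" for p in self.profiles)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "protein_id": p.protein_id,
                    "length": p.length,
                    "n_hits": p.count_total,
                    "count_primary": p.count_primary,
                    **{f"count_{name}": p.count_by_pattern.get(name, 0) for name in _BY_NAME},
                    "classification": p.classification,
                    "hits": ";".join(f"{h.pattern}@{h.start}" for h in p.hits),
                }
                for p in self.profiles
            ]
        )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (id, sequence) pairs; parse errors name the record index."""
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[tuple[str, str]] = []
    try:
        for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            records.append((rec.id, str(rec.seq)))
    except Exception as exc:  # malformed record
        raise ValueError(f"malformed FASTA {path.name!r} at record {len(records)}: {exc}") from exc
    return records


def profile_protein(
    protein_id: str,
    sequence: str,
    tier: str = "primary_only",
    overlap_policy: str = "non_overlapping_greedy",
) -> ProteinHemeProfile:
    patterns = (PRIMARY_PATTERN,) if tier == "primary_only" else PATTERNS
    hits = tuple(scan_motifs(sequence, patterns, overlap_policy))
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.pattern] = counts.get(h.pattern, 0) + 1
    count_primary = counts.get(PRIMARY_PATTERN.name, 0)
    classify_on = count_primary if tier == "primary_only" else len(hits)
    return ProteinHemeProfile(
        protein_id=protein_id,
        length=len(sequence),
        hits=hits,
        count_primary=count_primary,
        count_by_pattern=counts,
        classification=classify_protein(classify_on),
    )


def proteome_mhc_survey(
    proteome: str | Path | Iterable[tuple[str, str]],
    tier: str = "primary_only",
    overlap_policy: str = "non_overlapping_greedy",
) -> SurveyResult:
    """Profile every protein of a proteome for heme-attachment motifs.

    ``tier`` is ``primary_only`` (classification counts CxxCH hits only) or
    ``with_variants`` (combined count over all six patterns, overlaps resolved
    most-canonical-first under the greedy policy).
    """
    if tier not in ("primary_only", "with_variants"):
        raise ValueError(f"unknown tier {tier!r}")
    if isinstance(proteome, (str, Path)):
        records = read_fasta(proteome)
    else:
        records = list(proteome)
    profiles = []
    for idx, (pid, seq) in enumerate(records):
        try:
            profiles.append(profile_protein(pid, seq, tier, overlap_policy))
        except ValueError as exc:
            raise ValueError(f"record {idx} ({pid!r}): {exc}") from exc
    return SurveyResult(profiles=tuple(profiles), tier=tier)


# ---------------------------------------------------------------------------
# Assembly statistics
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_length_bp: int
    gc_percent: float
    n50_bp: int


def assembly_stats(contigs: str | Path | Iterable[tuple[str, str]]) -> AssemblyStats:
    """Contig count, total length, GC% and N50 of a nucleotide assembly.

    N50 is the length L of the contig at which the cumulative length of
    contigs sorted in descending order first reaches half the assembly total.
    GC is computed over unambiguous bases only (N excluded from the
    denominator).
    """
    if isinstance(contigs, (str, Path)):
        records = read_fasta(contigs)
    else:
        records = list(contigs)
    if not records:
        raise ValueError("assembly contains no contigs")
    lengths: list[int] = []
    gc = at = 0
    for idx, (cid, seq) in enumerate(records):
        seq = seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"contig {cid!r} (record {idx}) has non-ACGTN characters: {sorted(bad)}")
        lengths.append(len(seq))
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    total = sum(lengths)
    half = total / 2.0
    cumulative = 0
    n50 = 0
    for L in sorted(lengths, reverse=True):
        cumulative += L
        if cumulative >= half:
            n50 = L
            break
    gc_percent = 100.0 * gc / (gc + at) if gc + at else 0.0
    return AssemblyStats(
        n_contigs=len(records), total_length_bp=total, gc_percent=gc_percent, n50_bp=n50
    )


# ---------------------------------------------------------------------------
# Gene-panel presence/absence screening
# ---------------------------------------------------------------------------

#: Karlin-Altschul parameters for gapped BLOSUM62 with gap open 11 / extend 1
#: (the standard blastp scoring scheme).
_KA_LAMBDA = 0.267
_KA_K = 0.041

#: Default homology thresholds; presence requires e-value below, identity
#: strictly above, and (unless no-coverage mode) query coverage at or above.
DEFAULT_THRESHOLDS = {"evalue": 1e-4, "identity": 30.0, "coverage": 50.0}


@dataclasses.dataclass(frozen=True)
class PanelResult:
    gene: str
    query_id: str
    best_hit_id: str | None
    percent_identity: float
    evalue: float
    query_coverage: float
    score: float
    present: bool


def _passes_thresholds(
    identity: float,
    evalue: float,
    coverage: float,
    thresholds: Mapping[str, float],
    no_coverage: bool,
) -> bool:
    ok = identity > thresholds["identity"] and evalue < thresholds["evalue"]
    if not no_coverage:
        ok = ok and coverage >= thresholds["coverage"]
    return ok


def _sanitize_for_alignment(seq: str) -> str:
    """Map residues outside the BLOSUM62 alphabet to X and drop stops."""
    out = []
    for c in seq.upper():
        if c == "*":
            continue
        out.append(c if c in STANDARD_AA + "BZX" else "X")
    return "".join(out)


def _builtin_search(
    queries: list[tuple[str, str]],
    subjects: list[tuple[str, str]],
) -> dict[str, tuple[str | None, float, float, float, float]]:
    """Best local alignment of each query against every subject.

    Returns per query id: (best subject id, identity%, e-value, coverage%,
    raw score).  E-values use the Karlin-Altschul formula
    E = K * m * n * exp(-lambda * S) with m the query length and n the total
    proteome length.
    """
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    matrix = balign.SubstitutionMatrix.std_protein_matrix()
    db_length = sum(len(s) for _, s in subjects) or 1
    subject_seqs = [(sid, bseq.ProteinSequence(_sanitize_for_alignment(s))) for sid, s in subjects]

    results: dict[str, tuple[str | None, float, float, float, float]] = {}
    for qid, qseq_raw in queries:
        qclean = _sanitize_for_alignment(qseq_raw)
        qseq = bseq.ProteinSequence(qclean)
        best: tuple[float, str, object] | None = None
        for sid, sseq in subject_seqs:
            # gap cost 11 + L matches the blastp 11/1 convention (biotite
            # charges `open` for the first gap position)
            alns = balign.align_optimal(
                qseq, sseq, matrix, gap_penalty=(-12, -1), local=True, max_number=1
            )
            if not alns:
                continue
            aln = alns[0]
            if best is None or aln.score > best[0]:
                best = (float(aln.score), sid, aln)
        if best is None:
            results[qid] = (None, 0.0, math.inf, 0.0, 0.0)
            continue
        score, sid, aln = best
        trace = aln.trace
        n_cols = trace.shape[0]
        matches = 0
        for qi, si in trace:
            if qi >= 0 and si >= 0 and str(qseq)[qi] == str(aln.sequences[1])[si]:
                matches += 1
        identity = 100.0 * matches / n_cols if n_cols else 0.0
        q_positions = trace[:, 0][trace[:, 0] >= 0]
        span = int(q_positions.max() - q_positions.min() + 1) if q_positions.size else 0
        coverage = 100.0 * span / len(qclean) if qclean else 0.0
        evalue = _KA_K * len(qclean) * db_length * math.exp(-_KA_LAMBDA * score)
        results[qid] = (sid, identity, evalue, coverage, score)
    return results


def _blast_search(
    queries: list[tuple[str, str]],
    subjects: list[tuple[str, str]],
) -> dict[str, tuple[str | None, float, float, float, float]]:
    """Delegate the search to external makeblastdb/blastp."""
    if shutil.which("blastp") is None or shutil.which("makeblastdb") is None:
        raise RuntimeError("blastp/makeblastdb not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        qf, sf = tmp / "q.faa", tmp / "s.faa"
        for f, recs in ((qf, queries), (sf, subjects)):
            with open(f, "w") as fh:
                for rid, seq in recs:
                    fh.write(f">{rid}\n{_sanitize_for_alignment(seq)}\n")
        try:
            subprocess.run(
                ["makeblastdb", "-in", str(sf), "-dbtype", "prot"],
                check=True, capture_output=True, text=True,
            )
            proc = subprocess.run(
                [
                    "blastp", "-query", str(qf), "-db", str(sf),
                    "-outfmt", "6 qseqid sseqid pident evalue qstart qend bitscore",
                    "-max_target_seqs", "5",
                ],
                check=True, capture_output=True, text=True,
            )
        except subprocess.CalledProcessError as exc:
            raise RuntimeError(f"blast backend failed: {exc.stderr}") from exc
    qlen = {rid: len(_sanitize_for_alignment(seq)) for rid, seq in queries}
    results: dict[str, tuple[str | None, float, float, float, float]] = {
        rid: (None, 0.0, math.inf, 0.0, 0.0) for rid, _ in queries
    }
    for line in proc.stdout.splitlines():
        qid, sid, pident, evalue, qstart, qend, bitscore = line.split("\t")
        coverage = 100.0 * (int(qend) - int(qstart) + 1) / qlen[qid]
        record = (sid, float(pident), float(evalue), coverage, float(bitscore))
        if results[qid][0] is None or float(bitscore) > results[qid][4]:
            results[qid] = record
    return results


def panel_presence(
    queries: str | Path | Iterable[tuple[str, str]],
    proteome: str | Path | Iterable[tuple[str, str]],
    thresholds: Mapping[str, float] | None = None,
    no_coverage: bool = False,
    backend: str = "builtin",
) -> list[PanelResult]:
    """Presence/absence of gene-panel queries in a proteome.

    A gene is present when its best local-alignment hit clears e-value < 1e-4
    and identity > 30%; by default a query-coverage >= 50% requirement is
    added to suppress short spurious matches (``no_coverage=True`` disables
    it).  ``backend`` is ``builtin`` (BLOSUM62 local aligner) or ``blast``
    (external blastp, normalised to the same record).
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    if any(v <= 0 for v in thr.values()):
        raise ValueError("thresholds must be positive")
    q = read_fasta(queries) if isinstance(queries, (str, Path)) else list(queries)
    s = read_fasta(proteome) if isinstance(proteome, (str, Path)) else list(proteome)
    if not q:
        raise ValueError("empty query set")
    search = {"builtin": _builtin_search, "blast": _blast_search}.get(backend)
    if search is None:
        raise ValueError(f"unknown backend {backend!r}")
    hits = search(q, s) if s else {qid: (None, 0.0, math.inf, 0.0, 0.0) for qid, _ in q}
    out = []
    for qid, _ in q:
        sid, identity, evalue, coverage, score = hits[qid]
        gene = qid.split("|")[0]
        out.append(
            PanelResult(
                gene=gene,
                query_id=qid,
                best_hit_id=sid,
                percent_identity=identity,
                evalue=evalue,
                query_coverage=coverage,
                score=score,
                present=sid is not None
                and _passes_thresholds(identity, evalue, coverage, thr, no_coverage),
            )
        )
    return out
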