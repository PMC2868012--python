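"""Exact remapping of probe sequences to a genome.

Probe annotation files built on an outdated genome assembly leave probes
matching nowhere, or in several places, on the current assembly. This module
rebuilds the annotation by exact multi-pattern matching: all probe
sequences (and, by default, their reverse complements) are compiled into a
single Aho-Corasick automaton and the genome is streamed through it once.
Probes matching exactly one locus are kept; the rest are dropped and
counted as "none" or "multiple".

Matching is exact — no mismatches — and case-insensitive (the genome is
uppercased on read; soft-masked regions are not excluded). ``N`` in the
genome matches nothing: the automaton resets to the root. Probes whose own
sequence contains ``N`` are excluded up front and counted as "none".

Reverse-strand hits are found by augmenting the pattern set with reverse
complements rather than scanning a reverse-complemented genome; the results
are identical and the genome is traversed in a single pass.
"""

from __future__ import annotations

from collections import deque
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .datamodel import ProbeAnnotation, ProbeSet, reverse_complement

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

# A match is (chrom, forward-strand start, strand); MatchList maps
# probe index -> list of such triples, unique per probe.
Match = Tuple[str, int, str]
MatchList = Dict[int, List[Match]]


class Automaton:
    """Aho-Corasick automaton over the DNA alphabet {A,C,G,T}.

    States are integers, 0 is the root. ``goto[state]`` is a length-4 list of
    child states (-1 when absent), ``fail[state]`` the failure link, and
    ``out[state]`` the indices of patterns ending at that state (including
    those inherited through the failure chain). Duplicate pattern strings
    share one terminal state whose output carries every owner index.
    """

    def __init__(self, patterns: Sequence[str]):
        if not patterns:
            raise ValueError("empty pattern list")
        self.patterns = list(patterns)
        self.goto: List[List[int]] = [[-1, -1, -1, -1]]
        self.out: List[List[int]] = [[]]
        self.depth: List[int] = [0]
        for pat_idx, pat in enumerate(self.patterns):
            if not pat:
                raise ValueError("empty pattern")
            state = 0
            for ch in pat:
                ci = _BASE_INDEX.get(ch)
                if ci is None:
                    raise ValueError(f"illegal character {ch!r} in pattern {pat!r}")
                nxt = self.goto[state][ci]
                if nxt == -1:
                    nxt = len(self.goto)
                    self.goto.append([-1, -1, -1, -1])
                    self.out.append([])
                    self.depth.append(self.depth[state] + 1)
                    self.goto[state][ci] = nxt
                state = nxt
            self.out[state].append(pat_idx)
        self._build_failure_links()
        # transition counter for the linear-scan guarantee; incremented on
        # every goto step and every failure-link follow
        self.transitions = 0

    def _build_failure_links(self) -> None:
        n = len(self.goto)
        self.fail = [0] * n
        queue: deque[int] = deque()
        for ci in range(4):
            child = self.goto[0][ci]
            if child != -1:
                queue.append(child)  # fail of depth-1 states is root
        while queue:
            state = queue.popleft()
            # outputs of the failure target are also outputs here
            self.out[state] = self.out[state] + self.out[self.fail[state]]
            for ci in range(4):
                child = self.goto[state][ci]
                if child == -1:
                    continue
                f = self.fail[state]
                while f and self.goto[f][ci] == -1:
                    f = self.fail[f]
                t = self.goto[f][ci]
                self.fail[child] = t if (t != -1 and t != child) else 0
                queue.append(child)

    @property
    def n_states(self) -> int:
        return len(self.goto)

    def scan(self, text: str) -> Iterable[Tuple[int, int]]:
        """Yield (pattern_index, end_position_exclusive) for every occurrence.

        Characters outside {A,C,G,T} (notably N) reset the automaton to the
        root, so no match spans them.
        """
        goto, fail, out = self.goto, self.fail, self.out
        state = 0
        trans = 0
        for pos, ch in enumerate(text):
            ci = _BASE_INDEX.get(ch)
            if ci is None:
                state = 0
                continue
            while state and goto[state][ci] == -1:
                state = fail[state]
                trans += 1
            nxt = goto[state][ci]
            state = nxt if nxt != -1 else 0
            trans += 1
            if out[state]:
                end = pos + 1
                for pat_idx in out[state]:
                    yield pat_idx, end
        self.transitions += trans


def build_automaton(patterns: Sequence[str]) -> Automaton:
    """Compile a pattern set into an Aho-Corasick automaton.

    Duplicate strings share a terminal state but every pattern index is
    retained in its output set.
    """
    return Automaton(patterns)


def scan_genome(
    automaton_or_patterns,
    genome: Mapping[str, str],
    both_strands: bool = True,
    pattern_owners: Sequence[Tuple[int, str]] | None = None,
) -> MatchList:
    """Locate every exact occurrence of each probe sequence in a genome.

    ``genome`` maps chromosome name -> uppercase sequence. When
    ``both_strands`` is true, a hit of the reverse complement of probe P at
    forward interval [s, s+L) is reported as (chrom, s, '-').

    The convenient call passes the probe sequences directly; the automaton
    over patterns plus reverse complements is then built here. Callers who
    pre-build can pass ``pattern_owners`` mapping automaton pattern index ->
    (probe_index, strand).
    """
    if isinstance(automaton_or_patterns, Automaton):
        automaton = automaton_or_patterns
        if pattern_owners is None:
            pattern_owners = [(i, "+") for i in range(len(automaton.patterns))]
        owners = list(pattern_owners)
        n_probes = max(i for i, _ in owners) + 1
    else:
        sequences = list(automaton_or_patterns)
        n_probes = len(sequences)
        automaton, owners = _build_two_strand_automaton(sequences, both_strands)

    matches: MatchList = {i: [] for i in range(n_probes)}
    for chrom in sorted(genome):
        seq = genome[chrom]
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"chromosome {chrom} contains illegal characters {sorted(bad)!r}")
        for pat_idx, end in automaton.scan(seq):
            probe_idx, strand = owners[pat_idx]
            L = len(automaton.patterns[pat_idx])
            m = (chrom, end - L, strand)
            if m not in matches[probe_idx]:
                matches[probe_idx].append(m)
    return matches


def _build_two_strand_automaton(
    sequences: Sequence[str], both_strands: bool
) -> Tuple[Automaton, List[Tuple[int, str]]]:
    """Automaton over probe sequences (+ revcomps), skipping N-probes."""
    patterns: List[str] = []
    owners: List[Tuple[int, str]] = []
    for i, seq in enumerate(sequences):
        if "N" in seq:
            continue  # classified "none" downstream
        patterns.append(seq)
        owners.append((i, "+"))
        if both_strands:
            patterns.append(reverse_complement(seq))
            owners.append((i, "-"))
    if not patterns:
        raise ValueError("no scannable patterns (all probes contain N)")
    return Automaton(patterns), owners


def classify_matches(matches: MatchList, probes: ProbeSet) -> ProbeAnnotation:
    """Retain uniquely matching probes; count the rest.

    A probe with exactly one hit (on either strand) is kept. Zero hits count
    as "none"; two or more — including one forward plus one reverse hit of
    the same probe, as happens for palindromic sequences — count as
    "multiple". The report totals always sum to the probe-set size.
    """
    report = {"unique": 0, "none": 0, "multiple": 0}
    entries: Dict[str, List[Tuple[int, int, str]]] = {}
    for i in range(probes.n_probes):
        hits = matches.get(i, [])
        if len(hits) == 1:
            report["unique"] += 1
            chrom, start, strand = hits[0]
            entries.setdefault(chrom, []).append((i, start, strand))
        elif len(hits) == 0:
            report["none"] += 1
        else:
            report["multiple"] += 1
    for chrom in entries:
        entries[chrom].sort(key=lambda e: (e[1], e[0]))
    return ProbeAnnotation(
        entries=entries, match_report=report, probe_length=probes.probe_length
    )


def remap_probes(
    probes: ProbeSet, genome: Mapping[str, str], both_strands: bool = True
) -> ProbeAnnotation:
    """One-call remap: scan + classify."""
    matches = scan_genome([s for s in probes.sequences], genome, both_strands)
    return classify_matches(matches, probes)


def write_corrected_annotation(
    anno: ProbeAnnotation, probes: ProbeSet, path: str | Path
) -> None:
    """Write the corrected annotation table plus a sidecar match report.

    The table is tab-delimited (chrom, start0, strand, probe_id), sorted by
    chromosome then start; the report at ``<path>.report.txt`` carries the
    unique/none/multiple counts. Output is byte-deterministic.
    """
    path = Path(path)
    lines = ["chrom\tstart\tstrand\tprobe_id"]
    for chrom in sorted(anno.entries):
        for idx, start, strand in anno.entries[chrom]:
            lines.append(f"{chrom}\t{start}\t{strand}\t{probes.probe_ids[idx]}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    rep = anno.match_report
    report = (
        f"unique\t{rep['unique']}\nnone\t{rep['none']}\nmultiple\t{rep['multiple']}\n"
    )
    Path(str(path) + ".report.txt").write_text(report, encoding="utf-8", newline="\n")


def naive_scan(
    sequences: Sequence[str], genome: Mapping[str, str], both_strands: bool = True
) -> MatchList:
    """Per-pattern sliding-window search; independent oracle for scan_genome.

    Uses repeated ``str.find`` with step 1 so overlapping occurrences are
    found. N-probes are skipped (no hits), matching scan_genome's contract.
    """
    matches: MatchList = {i: [] for i in range(len(sequences))}
    for chrom in sorted(genome):
        seq = genome[chrom]
        for i, pat in enumerate(sequences):
            if "N" in pat:
                continue
            for start in _find_all(seq, pat):
                if _clean_window(seq, start, len(pat)):
                    matches[i].append((chrom, start, "+"))
            if both_strands:
                rc = reverse_complement(pat)
                for start in _find_all(seq, rc):
                    if _clean_window(seq, start, len(pat)):
                        m = (chrom, start, "-")
                        if m not in matches[i]:
                            matches[i].append(m)
    return matches


def _find_all(text: str, pat: str) -> Iterable[int]:
    start = text.find(pat)
    while start != -1:
        yield start
        start = text.find(pat, start + 1)


def _clean_window(seq: str, start: int, L: int) -> bool:
    return "N" not in seq[start : start + L]
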