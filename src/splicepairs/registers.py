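"""Five-register alignment of 15-nt windows against an 11-nt recognition loop.

The pilot grid procedure: a window covering the last 10 nt upstream and the
first 5 nt downstream of a declared boundary is superimposed on an 11-nt
loop in each of the five binding registers that keep the upstream (5'-exon
side) helix longer than the downstream one — splits 6+5, 7+4, 8+3, 9+2 and
10+1.  The register(s) with the most Watson–Crick pairs are chosen; ties
are reported, never broken.  A secondary score vector records the
mismatch-preference ordering (Watson–Crick, then G-U/U-G, U-U, C-U/U-C,
A-C/C-A, then non-isosteric) for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .pairing import (LoopModel, PairClass, PairObservation, classify_pair,
                      canonical_base, format_position, normalize_sequence,
                      pair_profile)

__all__ = [
    "RegisterAlignment",
    "ScanResult",
    "REGISTERS",
    "enumerate_registers",
    "scan_registers",
    "composition_summary",
    "scan_fasta_windows",
    "window_from_flanks",
]

WINDOW_LEN = 15
UPSTREAM_LEN = 10   # window positions 1..10 = upstream -10..-1
DOWNSTREAM_LEN = 5  # window positions 11..15 = downstream +1..+5
LOOP_LEN = 11

#: the five splits (upstream helix length, downstream helix length)
REGISTERS = [(6, 5), (7, 4), (8, 3), (9, 2), (10, 1)]


def _register_label(split: tuple[int, int]) -> str:
    return f"{split[0]}+{split[1]}"


def enumerate_registers(loop: LoopModel, window_len: int = WINDOW_LEN
                        ) -> dict[str, dict[str, int]]:
    """Pairing maps for the five registers of an 11-nt loop on a 15-nt window.

    Each map sends window position labels (``exon:-a..-1`` upstream,
    ``exon:+1..+b`` downstream) to loop position numbers, pairing the loop
    antiparallel: the highest loop position meets the 5'-most window
    position of the covered 11-nt stretch.
    """
    if window_len != WINDOW_LEN:
        raise ValueError(f"window length must be {WINDOW_LEN}")
    loop_desc = sorted(loop.residues, reverse=True)
    if len(loop_desc) != LOOP_LEN:
        raise ValueError(f"loop {loop.name} has {len(loop_desc)} residues, need {LOOP_LEN}")
    maps = {}
    for a, b in REGISTERS:
        labels = ([format_position("exon", -k) for k in range(a, 0, -1)]
                  + [format_position("exon", +k) for k in range(1, b + 1)])
        maps[_register_label((a, b))] = dict(zip(labels, loop_desc))
    return maps


@dataclass
class RegisterAlignment:
    """One window aligned to the loop in one register."""

    register: str
    observations: list[PairObservation]
    loop_name: str

    @property
    def wc_count(self) -> int:
        return sum(o.pair_class is PairClass.WATSON_CRICK for o in self.observations)

    @property
    def preference_vector(self) -> tuple[int, int, int, int, int, int]:
        """Counts ordered by the grid's mismatch preference.

        (WC, G-U/U-G, U-U, C-U/U-C, A-C/C-A, non-isosteric) — reported for
        tie inspection, never used to choose a register.
        """
        buckets = [0] * 6
        order = {frozenset("GU"): 1, frozenset("U"): 2,
                 frozenset("CU"): 3, frozenset("AC"): 4}
        for o in self.observations:
            if o.pair_class is PairClass.WATSON_CRICK:
                buckets[0] += 1
            elif o.pair_class is PairClass.NON_ISOSTERIC:
                buckets[5] += 1
            else:
                key = frozenset((o.substrate_base.code, o.loop_base.code))
                buckets[order[key]] += 1
        return tuple(buckets)


@dataclass
class ScanResult:
    """All five register alignments of one window, with the chosen maxima."""

    window: str
    alignments: dict[str, RegisterAlignment]

    @property
    def best_registers(self) -> list[str]:
        best = max(a.wc_count for a in self.alignments.values())
        return [r for r, a in self.alignments.items() if a.wc_count == best]

    @property
    def unambiguous(self) -> bool:
        return len(self.best_registers) == 1

    @property
    def wc_counts(self) -> dict[str, int]:
        return {r: a.wc_count for r, a in self.alignments.items()}


def scan_registers(window: str, loop: LoopModel) -> ScanResult:
    """Score a 15-nt window (declared boundary at 10|11) in all five registers."""
    if len(window) != WINDOW_LEN:
        raise ValueError(f"window length {len(window)} != {WINDOW_LEN}")
    rna = normalize_sequence(window)
    labels = ([format_position("exon", -k) for k in range(UPSTREAM_LEN, 0, -1)]
              + [format_position("exon", +k) for k in range(1, DOWNSTREAM_LEN + 1)])
    substrate = dict(zip(labels, rna))
    alignments = {}
    for register, pairing in enumerate_registers(loop).items():
        sub_model = LoopModel(name=loop.name, residues=loop.residues,
                              pairing_map=pairing)
        obs = pair_profile(substrate, sub_model)
        alignments[register] = RegisterAlignment(
            register=register, observations=obs, loop_name=loop.name)
    return ScanResult(window=rna, alignments=alignments)


def composition_summary(alignments: list[RegisterAlignment]) -> pd.DataFrame:
    """Base-pair composition of a set of chosen alignments.

    Returns a tidy table with one row per unordered pair identity:
    columns ``pair`` (e.g. ``"G:C"``), ``pair_class``, ``count``,
    ``percent``.  Counts sum to 11 x len(alignments).
    """
    if not alignments:
        raise ValueError("empty alignment collection")
    loops = {a.loop_name for a in alignments}
    if len(loops) > 1:
        raise ValueError(f"mixed loop models in summary: {sorted(loops)}")
    counts: dict[str, int] = {}
    classes: dict[str, PairClass] = {}
    for a in alignments:
        for o in a.observations:
            pair = ":".join(sorted((o.substrate_base.code, o.loop_base.code)))
            counts[pair] = counts.get(pair, 0) + 1
            classes[pair] = o.pair_class
    total = sum(counts.values())
    df = pd.DataFrame(
        [{"pair": p, "pair_class": classes[p].value, "count": c,
          "percent": 100.0 * c / total} for p, c in counts.items()]
    ).sort_values("count", ascending=False, ignore_index=True)
    df.attrs["n_pairs"] = total
    df.attrs["n_alignments"] = len(alignments)
    return df


def window_from_flanks(upstream: str, downstream: str) -> str:
    """Build a 15-nt scan window from flanking sequences around a boundary.

    Takes the last 10 nt of ``upstream`` and the first 5 nt of
    ``downstream``; both must be long enough.
    """
    if len(upstream) < UPSTREAM_LEN:
        raise ValueError(f"upstream flank needs >= {UPSTREAM_LEN} nt, got {len(upstream)}")
    if len(downstream) < DOWNSTREAM_LEN:
        raise ValueError(f"downstream flank needs >= {DOWNSTREAM_LEN} nt, got {len(downstream)}")
    return upstream[-UPSTREAM_LEN:] + downstream[:DOWNSTREAM_LEN]


def scan_fasta_windows(path, loop: LoopModel) -> pd.DataFrame:
    """Scan every 15-nt window in a FASTA file against a loop model.

    The declared boundary is at window position 10|11.  Returns one row per
    record: best registers (comma-joined), wc counts per register, and an
    ambiguity flag.
    """
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        res = scan_registers(str(rec.seq), loop)
        row = {"id": rec.id, "best_registers": ",".join(res.best_registers),
               "unambiguous": res.unambiguous}
        row.update({f"wc_{r}": c for r, c in res.wc_counts.items()})
        rows.append(row)
    return pd.DataFrame(rows)
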