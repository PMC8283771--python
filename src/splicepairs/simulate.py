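"""Synthetic splice-site dataset generator.

Generates intron records with the statistical structure the analysis
assumes: independent per-position nucleotide distributions shaped like the
human major-spliceosome consensus (exon-end G ~82 %, intron +5G ~80 %,
exon-start G ~50 %, pyrimidine-rich intron end, GT..AG termini enforced),
plus tunable dependencies between conserved positions:

* ``delta_5ss`` — conditional on the intron lacking +5G, the exon -1
  guanine probability is raised so that
  P(-1G | +5 substituted) - P(-1G | +5G) = delta_5ss while the -1G
  marginal is preserved;
* ``delta_3ss`` — the same construction between intron -3C and the
  exon-start guanine (+1G).

With both deltas zero, exon-side and intron-side positions are independent
by construction.  The generator emulates marginal consensus frequencies and
these pairwise dependencies only — not branchpoints, splicing regulation,
dinucleotide composition or any further linkage of real genomes.

The default vectors are configuration data approximating the human splice
site consensus, not claims about the genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import IntronRecord, SpliceDataset

__all__ = ["SiteFrequencyModel", "generate_dataset", "make_null_pair"]

_NUCS = np.array(list("ACGT"))
_IDX = {c: i for i, c in enumerate("ACGT")}


def _v(a: float, c: float, g: float, t: float) -> np.ndarray:
    return np.array([a, c, g, t], dtype=float)


def _default_exon5() -> dict[int, np.ndarray]:
    base = {k: _v(0.27, 0.23, 0.27, 0.23) for k in range(-8, -3)}
    base[-3] = _v(0.33, 0.36, 0.16, 0.15)   # C/A near 1:1, the U1/U5 crossroads
    base[-2] = _v(0.60, 0.13, 0.14, 0.13)
    base[-1] = _v(0.09, 0.04, 0.82, 0.05)   # exon-end G ~82 % conserved
    return base


def _default_exon3() -> dict[int, np.ndarray]:
    return {
        1: _v(0.25, 0.12, 0.50, 0.13),      # half of human exons start with G
        2: _v(0.30, 0.25, 0.20, 0.25),
        3: _v(0.25, 0.25, 0.25, 0.25),
    }


def _default_intron_start() -> dict[int, np.ndarray]:
    return {
        1: _v(0, 0, 1.0, 0),                # G (GT terminus enforced)
        2: _v(0, 0, 0, 1.0),                # T
        3: _v(0.60, 0.07, 0.25, 0.08),
        4: _v(0.70, 0.08, 0.12, 0.10),
        5: _v(0.08, 0.05, 0.80, 0.07),      # one in five introns lacks +5G
        6: _v(0.20, 0.15, 0.20, 0.45),
        7: _v(0.25, 0.20, 0.25, 0.30),
        8: _v(0.25, 0.20, 0.25, 0.30),
        9: _v(0.25, 0.20, 0.25, 0.30),
        10: _v(0.25, 0.20, 0.25, 0.30),
    }


def _default_intron_end() -> dict[int, np.ndarray]:
    return {
        -6: _v(0.15, 0.30, 0.15, 0.40),
        -5: _v(0.15, 0.30, 0.15, 0.40),
        -4: _v(0.15, 0.30, 0.15, 0.40),
        -3: _v(0.12, 0.60, 0.06, 0.22),     # -3C majority
        -2: _v(1.0, 0, 0, 0),               # A (AG terminus enforced)
        -1: _v(0, 0, 1.0, 0),               # G
    }


@dataclass
class SiteFrequencyModel:
    """Positional nucleotide probabilities (A, C, G, T order) and dependencies."""

    exon5: dict[int, np.ndarray] = field(default_factory=_default_exon5)
    exon3: dict[int, np.ndarray] = field(default_factory=_default_exon3)
    intron_start: dict[int, np.ndarray] = field(default_factory=_default_intron_start)
    intron_end: dict[int, np.ndarray] = field(default_factory=_default_intron_end)
    background: np.ndarray = field(
        default_factory=lambda: _v(0.15, 0.30, 0.15, 0.40))  # pyrimidine-rich fill
    delta_5ss: float = 0.0
    delta_3ss: float = 0.0
    intron_end_len: int = 60

    def validate(self) -> None:
        for name, table in (("exon5", self.exon5), ("exon3", self.exon3),
                            ("intron_start", self.intron_start),
                            ("intron_end", self.intron_end)):
            for pos, vec in table.items():
                if vec.shape != (4,) or np.any(vec < 0) or not np.isclose(vec.sum(), 1.0):
                    raise ValueError(
                        f"invalid probability vector {name}[{pos}] = {vec}")
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError(f"invalid background vector {self.background}")

    # -- dependency construction -------------------------------------------

    def _shifted(self, vec: np.ndarray, target: str, shift: float) -> np.ndarray:
        """Move ``shift`` probability mass onto ``target``, pro-rata from the rest."""
        out = vec.copy()
        k = _IDX[target]
        new = out[k] + shift
        if not 0.0 <= new <= 1.0:
            warnings.warn(f"dependency shift clips P({target}) = {new:.3f} into [0, 1]")
            new = float(np.clip(new, 0.0, 1.0))
        rest = 1.0 - out[k]
        scale = (1.0 - new) / rest if rest > 0 else 0.0
        out *= scale
        out[k] = new
        return out

    def conditional_pair(self, vec: np.ndarray, target: str, delta: float,
                         p_conserved: float) -> tuple[np.ndarray, np.ndarray]:
        """(vector | partner conserved, vector | partner substituted).

        The split preserves the marginal: the substituted branch gains
        ``delta * p_conserved`` on the target nucleotide, the conserved
        branch loses ``delta * (1 - p_conserved)``, so the difference is
        exactly ``delta``.
        """
        cons = self._shifted(vec, target, -delta * (1.0 - p_conserved))
        sub = self._shifted(vec, target, +delta * p_conserved)
        return cons, sub


def _draw(rng: np.random.Generator, vec: np.ndarray, n: int) -> np.ndarray:
    return rng.choice(4, size=n, p=vec / vec.sum())


def generate_dataset(model: SiteFrequencyModel, n: int,
                     seed: int | None = None) -> SpliceDataset:
    """Draw ``n`` synthetic major-spliceosome intron records."""
    model.validate()
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)

    start_positions = sorted(model.intron_start)
    start = np.stack([_draw(rng, model.intron_start[p], n) for p in start_positions],
                     axis=1) if n else np.empty((0, len(start_positions)), int)
    end_positions = sorted(model.intron_end)  # -6..-1
    end_expl = np.stack([_draw(rng, model.intron_end[p], n) for p in end_positions],
                        axis=1) if n else np.empty((0, len(end_positions)), int)

    # exon positions, -1 and +1 conditioned on +5 / -3 when deltas are set
    exon5_positions = sorted(model.exon5)
    exon5 = np.empty((n, len(exon5_positions)), dtype=int)
    for j, pos in enumerate(exon5_positions):
        vec = model.exon5[pos]
        if pos == -1 and model.delta_5ss != 0.0 and n:
            plus5 = start[:, start_positions.index(5)]
            has_g = plus5 == _IDX["G"]
            p_cons = float(model.intron_start[5][_IDX["G"]])
            cons, sub = model.conditional_pair(vec, "G", model.delta_5ss, p_cons)
            exon5[:, j] = np.where(has_g, _draw(rng, cons, n), 0)
            n_sub = int((~has_g).sum())
            if n_sub:
                exon5[~has_g, j] = _draw(rng, sub, n_sub)
        else:
            exon5[:, j] = _draw(rng, vec, n)

    exon3_positions = sorted(model.exon3)
    exon3 = np.empty((n, len(exon3_positions)), dtype=int)
    for j, pos in enumerate(exon3_positions):
        vec = model.exon3[pos]
        if pos == 1 and model.delta_3ss != 0.0 and n:
            minus3 = end_expl[:, end_positions.index(-3)]
            has_c = minus3 == _IDX["C"]
            p_cons = float(model.intron_end[-3][_IDX["C"]])
            cons, sub = model.conditional_pair(vec, "G", model.delta_3ss, p_cons)
            exon3[:, j] = np.where(has_c, _draw(rng, cons, n), 0)
            n_sub = int((~has_c).sum())
            if n_sub:
                exon3[~has_c, j] = _draw(rng, sub, n_sub)
        else:
            exon3[:, j] = _draw(rng, vec, n)

    fill_len = model.intron_end_len - len(end_positions)
    fill = (rng.choice(4, size=(n, fill_len), p=model.background)
            if n else np.empty((0, fill_len), int))

    records = []
    for i in range(n):
        junction = "".join(_NUCS[exon5[i]]) + "".join(_NUCS[exon3[i]])
        records.append(IntronRecord(
            gene_id=f"SYNG{i:05d}",
            transcript_id=f"SYNT{i:05d}",
            intron_index=1,
            junction11=junction,
            intron_start10="".join(_NUCS[start[i]]),
            intron_end60="".join(_NUCS[fill[i]]) + "".join(_NUCS[end_expl[i]]),
            spliceosome_class="major",
        ))
    return SpliceDataset(records=records, provenance={
        "generator": "splicepairs.simulate.generate_dataset",
        "n": n, "seed": seed,
        "delta_5ss": model.delta_5ss, "delta_3ss": model.delta_3ss,
    })


def make_null_pair(model: SiteFrequencyModel, n_a: int, n_b: int,
                   seed: int | None = None) -> tuple[SpliceDataset, SpliceDataset]:
    """Two datasets drawn from one distribution (for type-I calibration)."""
    if n_a < 1 or n_b < 1:
        raise ValueError("both sizes must be >= 1")
    children = np.random.SeedSequence(seed).spawn(2)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    return (generate_dataset(model, n_a, seed=seeds[0]),
            generate_dataset(model, n_b, seed=seeds[1]))
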