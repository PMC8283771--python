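"""Resampling statistics over positional base-pair class frequencies.

This is the analytical core of the pipeline:

* per-position frequencies of the three base-pair geometry classes for a
  set of splice-site records paired against a recognition-loop model;
* symmetrized Kullback–Leibler (sKL) divergence between two such frequency
  profiles over position subsites, with a resampling control built from
  pairs of disjoint random subsets of the larger group;
* bootstrap difference (BD) tests of each (position, class) frequency
  between two groups, with the null-hypothesis probability P(H0) defined
  as the smaller tail of the BD distribution beyond zero;
* a per-nucleotide variant of the bootstrap at a single position;
* Bonferroni–Dunn alpha splitting, plain and adjusted for correlated tests
  via m' = (m+1) - [1 + (m-1)R] applied groupwise.

Class frequencies at a position are three-valued only where the loop
partner admits all three geometries; positions whose loop partner is a
uridine can never produce a non-isosteric pair and carry two defined
classes.  All undefined cells are masked out of testing and counting.

P(H0) and the two-sided p-value
-------------------------------
``p_h0`` is the smaller-tail fraction min(#{BD<=0}, #{BD>=0})/iterations
(ties counted in both tails).  Significance calls against Dunn thresholds
use ``p_h0``, matching the published procedure.  Under a true null the
smaller tail falls below alpha with probability ~2*alpha, so the result
object also carries the standard two-sided bootstrap p-value
``p_value = min(1, 2 * p_h0)`` whose type-I error rate is the nominal
alpha; calibration checks use ``p_value``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import IntronRecord
from .pairing import LoopModel, PairClass, classify_pair, parse_position

__all__ = [
    "CLASS_ORDER",
    "ClassMatrix",
    "PairClassDistribution",
    "SubsiteSpec",
    "SKLResult",
    "BootstrapResult",
    "NucleotideBootstrapResult",
    "CorrectionPlan",
    "class_matrix",
    "position_frequencies",
    "skl_divergence",
    "skl_control_experiment",
    "bootstrap_differences",
    "nucleotide_bootstrap",
    "dunn_threshold",
    "adjusted_m",
    "build_correction_plan",
    "default_subsites",
]

CLASS_ORDER = ("watson_crick", "isosteric", "non_isosteric")
_NUCS = "ACGU"
_CHUNK = 2000  # bootstrap iterations per vectorized block


# ---------------------------------------------------------------------------
# class matrices
# ---------------------------------------------------------------------------

def _junction_index(label: str) -> tuple[str, int]:
    """Map a substrate label to (record field, string index)."""
    side, off = parse_position(label)
    if side == "exon":
        return ("junction11", 8 + off) if off < 0 else ("junction11", 7 + off)
    if off > 0:
        return "intron_start10", off - 1
    return "intron_end60", off  # negative: index from the end


@dataclass
class ClassMatrix:
    """Per-record, per-position base-pair class codes for one loop model.

    ``codes[i, j]`` is 0/1/2 for watson_crick/isosteric/non_isosteric of
    record i at position j; ``nucleotides[i, j]`` is 0..3 for A/C/G/U.
    """

    codes: np.ndarray
    nucleotides: np.ndarray
    positions: list[str]
    defined: np.ndarray  # (P, 3) bool — classes realizable at each position
    model_name: str

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    def onehot(self) -> np.ndarray:
        """(N, P, 3) float32 indicator of the class at each cell."""
        out = np.zeros((*self.codes.shape, 3), dtype=np.float32)
        np.put_along_axis(out, self.codes[..., None].astype(np.intp), 1.0, axis=2)
        return out

    def nucleotide_onehot(self, position: str) -> np.ndarray:
        """(N, 4) float32 indicator of A/C/G/U at one position."""
        j = self.positions.index(position)
        out = np.zeros((self.n, 4), dtype=np.float32)
        out[np.arange(self.n), self.nucleotides[:, j].astype(np.intp)] = 1.0
        return out

    def subset(self, idx: np.ndarray) -> "ClassMatrix":
        return ClassMatrix(codes=self.codes[idx], nucleotides=self.nucleotides[idx],
                           positions=self.positions, defined=self.defined,
                           model_name=self.model_name)


def class_matrix(records: list[IntronRecord], model: LoopModel) -> ClassMatrix:
    """Pair every record against the loop model and encode class codes."""
    if not records:
        raise ValueError("empty record set")
    positions = model.ordered_labels
    cls_idx = {c: k for k, c in enumerate(CLASS_ORDER)}
    # per position: lookup tables nucleotide letter -> class code / nuc code
    tables = []
    defined = np.zeros((len(positions), 3), dtype=bool)
    for j, label in enumerate(positions):
        partner = model.partner_base(label)
        table = {}
        for ch in "ACGT U".replace(" ", ""):
            pc = classify_pair(ch, partner)
            table[ch] = (cls_idx[pc.value], _NUCS.index(ch if ch != "T" else "U"))
            defined[j, cls_idx[pc.value]] = True
        tables.append(table)

    codes = np.empty((len(records), len(positions)), dtype=np.int8)
    nucs = np.empty_like(codes)
    for i, rec in enumerate(records):
        for j, label in enumerate(positions):
            fieldname, k = _junction_index(label)
            seq = getattr(rec, fieldname)
            try:
                ch = seq[k].upper()
                code, nuc = tables[j][ch]
            except (IndexError, KeyError):
                raise ValueError(
                    f"record {rec.record_id}: cannot read position {label} "
                    f"from {fieldname}={seq!r}"
                ) from None
            codes[i, j] = code
            nucs[i, j] = nuc
    return ClassMatrix(codes=codes, nucleotides=nucs, positions=positions,
                       defined=defined, model_name=model.name)


def _as_matrix(records, model: LoopModel | None) -> ClassMatrix:
    if isinstance(records, ClassMatrix):
        return records
    if model is None:
        raise ValueError("a LoopModel is required when passing raw records")
    return class_matrix(records, model)


# ---------------------------------------------------------------------------
# frequencies and sKL divergence
# ---------------------------------------------------------------------------

@dataclass
class PairClassDistribution:
    """Per-position probability vectors over the three geometry classes."""

    positions: list[str]
    probs: np.ndarray   # (P, 3)
    defined: np.ndarray  # (P, 3) bool
    n: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, index=self.positions, columns=CLASS_ORDER)
        df.index.name = "position"
        return df

    def subsite(self, positions: list[str]) -> np.ndarray:
        idx = [self.positions.index(p) for p in positions]
        return self.probs[idx]


def position_frequencies(records, model: LoopModel | None = None) -> PairClassDistribution:
    """Observed class frequencies (count/N) at each mapped position."""
    m = _as_matrix(records, model)
    if m.n == 0:
        raise ValueError("empty record set")
    probs = m.onehot().mean(axis=0).astype(float)
    return PairClassDistribution(positions=list(m.positions), probs=probs,
                                 defined=m.defined.copy(), n=m.n)


def skl_divergence(p: np.ndarray, q: np.ndarray, increment: float = 1e-4) -> float:
    """Symmetrized KL divergence sum(p log2 p/q + q log2 q/p).

    The increment is added to every probability (without renormalization)
    to avoid division by zero, exactly as in the published procedure.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    pi = p + increment
    qi = q + increment
    ratio = np.log2(pi / qi)
    return float(np.sum(pi * ratio - qi * ratio))


@dataclass(frozen=True)
class SubsiteSpec:
    """A named group of adjacent positions over which sKL is accumulated."""

    name: str
    positions: tuple[str, ...]


def default_subsites(model_name: str) -> list[SubsiteSpec]:
    """The published subsite groupings for the U5 and U6 binding sites."""
    if model_name == "U5_loop1":
        return [
            SubsiteSpec("exon_-8..-6", ("exon:-8", "exon:-7", "exon:-6")),
            SubsiteSpec("exon_-5..-3", ("exon:-5", "exon:-4", "exon:-3")),
            SubsiteSpec("exon_-2..-1", ("exon:-2", "exon:-1")),
            SubsiteSpec("exon_+1..+3", ("exon:+1", "exon:+2", "exon:+3")),
        ]
    if model_name == "U6_acagaga":
        return [
            SubsiteSpec("intron_+5..+6", ("intron:+5", "intron:+6")),
            SubsiteSpec("intron_+7..+8", ("intron:+7", "intron:+8")),
            SubsiteSpec("intron_+9..+10", ("intron:+9", "intron:+10")),
        ]
    raise ValueError(f"no default subsites for model {model_name!r}")


@dataclass
class SKLResult:
    """Case and control sKL distributions for one subsite."""

    subsite: str
    case_values: np.ndarray
    control_values: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def mean_ratio(self) -> float:
        """phi: mean case sKL over mean control sKL.

        Infinite when the control distribution is exactly zero (degenerate
        inputs with no variation at the subsite) but the case is not; NaN
        when both are zero.
        """
        case = float(self.case_values.mean())
        control = float(self.control_values.mean())
        if control == 0.0:
            return math.nan if case == 0.0 else math.inf
        return case / control


def skl_control_experiment(
    reference_set,
    case_set,
    subsites: list[SubsiteSpec] | None = None,
    model: LoopModel | None = None,
    iterations: int = 10_000,
    seed: int | None = None,
    increment: float = 1e-4,
) -> dict[str, SKLResult]:
    """sKL divergence of a case group from a reference, with resampling control.

    Each iteration draws two disjoint random subsets of size ``len(case_set)``
    from the reference (indices sampled without replacement — subsets are
    non-redundant, the pair non-overlapping).  The control value is the sKL
    between the two subsets' subsite distributions; the case value is the
    sKL between the first subset and the case group.  The same subset pair
    is reused across subsites within an iteration.
    """
    ref = _as_matrix(reference_set, model)
    case = _as_matrix(case_set, model)
    n_case = case.n
    if ref.n < 2 * n_case:
        raise ValueError(
            f"reference too small: need >= {2 * n_case} records "
            f"(2 x case size), got {ref.n}"
        )
    if subsites is None:
        subsites = default_subsites(ref.model_name)
    rng = np.random.default_rng(seed)

    oh = ref.onehot().reshape(ref.n, -1)  # (N, P*3)
    case_dist = position_frequencies(case)
    pos_index = {p: j for j, p in enumerate(ref.positions)}
    sub_cols = {
        s.name: np.concatenate([np.arange(3 * pos_index[p], 3 * pos_index[p] + 3)
                                for p in s.positions])
        for s in subsites
    }
    case_flat = case_dist.probs.reshape(-1)

    case_vals = {s.name: np.empty(iterations) for s in subsites}
    ctrl_vals = {s.name: np.empty(iterations) for s in subsites}
    for start in range(0, iterations, _CHUNK):
        stop = min(start + _CHUNK, iterations)
        block = stop - start
        keys = rng.random((block, ref.n))
        take = np.argpartition(keys, 2 * n_case - 1, axis=1)[:, :2 * n_case]
        for b in range(block):
            idx = take[b]
            f1 = oh[idx[:n_case]].mean(axis=0)
            f2 = oh[idx[n_case:]].mean(axis=0)
            for s in subsites:
                cols = sub_cols[s.name]
                ctrl_vals[s.name][start + b] = skl_divergence(
                    f1[cols], f2[cols], increment)
                case_vals[s.name][start + b] = skl_divergence(
                    f1[cols], case_flat[cols], increment)

    prov = {"iterations": iterations, "seed": seed, "case_n": n_case,
            "reference_n": ref.n, "increment": increment,
            "subset_drawing": "joint per iteration across subsites"}
    return {s.name: SKLResult(subsite=s.name, case_values=case_vals[s.name],
                              control_values=ctrl_vals[s.name],
                              provenance=dict(prov))
            for s in subsites}


# ---------------------------------------------------------------------------
# bootstrap difference tests
# ---------------------------------------------------------------------------

def _tail_p(bd: np.ndarray) -> np.ndarray:
    """Smaller-tail fraction per cell; ties (BD == 0) count in both tails."""
    iters = bd.shape[0]
    lo = (bd <= 0).sum(axis=0)
    hi = (bd >= 0).sum(axis=0)
    return np.minimum(lo, hi) / iters


@dataclass
class BootstrapResult:
    """Bootstrap-difference distributions per (position, class)."""

    positions: list[str]
    bd: np.ndarray        # (iterations, P, 3)
    defined: np.ndarray   # (P, 3)
    iterations: int
    seed: int | None
    n_a: int
    n_b: int
    model_name: str

    @property
    def p_h0(self) -> np.ndarray:
        """(P, 3) smaller-tail null probability; NaN where undefined."""
        p = _tail_p(self.bd.reshape(self.iterations, -1)).reshape(self.defined.shape)
        return np.where(self.defined, p, np.nan)

    @property
    def p_value(self) -> np.ndarray:
        """(P, 3) two-sided bootstrap p-value min(1, 2*p_h0)."""
        return np.minimum(1.0, 2.0 * self.p_h0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy P(H0) table, one row per defined (position, class) cell."""
        ph0 = self.p_h0
        pv = self.p_value
        mean_bd = self.bd.mean(axis=0)
        rows = []
        for j, pos in enumerate(self.positions):
            for k, cls in enumerate(CLASS_ORDER):
                if self.defined[j, k]:
                    rows.append({"position": pos, "pair_class": cls,
                                 "mean_bd": mean_bd[j, k],
                                 "p_h0": ph0[j, k], "p_value": pv[j, k]})
        return pd.DataFrame(rows)

    def cell(self, position: str, pair_class: str) -> np.ndarray:
        j = self.positions.index(position)
        k = CLASS_ORDER.index(pair_class)
        if not self.defined[j, k]:
            raise ValueError(f"{pair_class} is undefined at {position}")
        return self.bd[:, j, k]


def _boot_freqs(oh_flat: np.ndarray, n: int, iterations: int,
                rng: np.random.Generator) -> np.ndarray:
    """Frequencies of (iterations) resamples-with-replacement of n records.

    Resampling record indices with replacement is realized as multinomial
    weights over records, which is exact and vectorizes as a matmul.
    """
    out = np.empty((iterations, oh_flat.shape[1]), dtype=np.float64)
    p = np.full(n, 1.0 / n)
    for start in range(0, iterations, _CHUNK):
        stop = min(start + _CHUNK, iterations)
        w = rng.multinomial(n, p, size=stop - start).astype(np.float64)
        out[start:stop] = (w @ oh_flat) / n
    return out


def bootstrap_differences(
    set_a,
    set_b,
    model: LoopModel | None = None,
    iterations: int = 10_000,
    seed: int | None = None,
) -> BootstrapResult:
    """Bootstrap the difference of every (position, class) frequency.

    Each iteration independently resamples group A at size |A| and group B
    at size |B| with replacement and records BD = freq_A* - freq_B* for
    every defined cell.
    """
    a = _as_matrix(set_a, model)
    b = _as_matrix(set_b, model)
    if a.n == 0 or b.n == 0:
        raise ValueError("both groups must be non-empty")
    if a.positions != b.positions:
        raise ValueError("groups were paired against different position sets")
    rng = np.random.default_rng(seed)
    fa = _boot_freqs(a.onehot().reshape(a.n, -1).astype(np.float64), a.n,
                     iterations, rng)
    fb = _boot_freqs(b.onehot().reshape(b.n, -1).astype(np.float64), b.n,
                     iterations, rng)
    bd = (fa - fb).reshape(iterations, len(a.positions), 3)
    return BootstrapResult(positions=list(a.positions), bd=bd,
                           defined=a.defined & b.defined, iterations=iterations,
                           seed=seed, n_a=a.n, n_b=b.n, model_name=a.model_name)


@dataclass
class NucleotideBootstrapResult:
    """Per-nucleotide bootstrap differences at a single position."""

    position: str
    bd: np.ndarray  # (iterations, 4) in A, C, G, U order
    iterations: int
    seed: int | None

    @property
    def p_h0(self) -> dict[str, float]:
        p = _tail_p(self.bd)
        return {nuc: float(p[k]) for k, nuc in enumerate(_NUCS)}

    @property
    def p_value(self) -> dict[str, float]:
        return {nuc: min(1.0, 2.0 * p) for nuc, p in self.p_h0.items()}


def nucleotide_bootstrap(
    position: str,
    set_a,
    set_b,
    model: LoopModel | None = None,
    iterations: int = 10_000,
    seed: int | None = None,
) -> NucleotideBootstrapResult:
    """Bootstrap A/C/G/U frequency differences at one position.

    Used at exon -3, where U1 and U5 require different nucleotides for a
    Watson–Crick pair, so the class-level test cannot separate them.
    """
    a = _as_matrix(set_a, model)
    b = _as_matrix(set_b, model)
    if position not in a.positions:
        raise ValueError(f"position {position!r} not covered by the model")
    rng = np.random.default_rng(seed)
    fa = _boot_freqs(a.nucleotide_onehot(position).astype(np.float64), a.n,
                     iterations, rng)
    fb = _boot_freqs(b.nucleotide_onehot(position).astype(np.float64), b.n,
                     iterations, rng)
    return NucleotideBootstrapResult(position=position, bd=fa - fb,
                                     iterations=iterations, seed=seed)


# ---------------------------------------------------------------------------
# Bonferroni–Dunn correction
# ---------------------------------------------------------------------------

def dunn_threshold(m: int, alpha: float = 0.05) -> tuple[float, float]:
    """Dunn's alpha splitting: alpha' = alpha / m.

    Returns (full precision, rounded to 4 decimals) — the rounded form is
    the conventional presentation.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    full = alpha / m
    return full, round(full, 4)


def adjusted_m(groups: list[tuple[int, float]]) -> int:
    """Correlation-adjusted effective test count.

    For each group of ``size`` correlated tests with interclass correlation
    ``R``, m' = (size+1) - [1 + (size-1) R]; group results are rounded to
    the nearest integer and summed.
    """
    total = 0
    for size, r in groups:
        if size < 1:
            raise ValueError(f"group size must be >= 1, got {size}")
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"interclass correlation must be in [0, 1], got {r}")
        mp = (size + 1) - (1 + (size - 1) * r)
        total += math.floor(mp + 0.5)
    return total


_DEFAULT_R = {2: 1.0, 3: 0.5, 4: 0.33}


@dataclass
class CorrectionPlan:
    """Multiple-testing accounting for one experiment."""

    m: int
    groups: list[tuple[int, float]]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.m != sum(size for size, _ in self.groups):
            raise ValueError(
                f"m = {self.m} does not equal the sum of group sizes "
                f"({sum(s for s, _ in self.groups)})"
            )

    @property
    def m_prime(self) -> int:
        return adjusted_m(self.groups)

    @property
    def alpha_prime(self) -> float:
        return dunn_threshold(self.m, self.alpha)[1]

    @property
    def alpha_prime_adjusted(self) -> float:
        return dunn_threshold(self.m_prime, self.alpha)[1]


def build_correction_plan(
    model: LoopModel,
    extra_tests: list[tuple[int, float]] | None = None,
    alpha: float = 0.05,
) -> CorrectionPlan:
    """Count bootstrap tests for a loop model's binding site.

    Positions whose loop partner is a uridine admit two pair classes (two
    perfectly correlated tests, R = 1); all others admit three (R = 0.5).
    ``extra_tests`` appends further groups, e.g. (4, 0.33) for the four
    nucleotide-level tests at exon -3.
    """
    groups = []
    for label in model.ordered_labels:
        size = 2 if model.partner_base(label).code == "U" else 3
        groups.append((size, _DEFAULT_R[size]))
    for size, r in (extra_tests or []):
        groups.append((size, r))
    m = sum(size for size, _ in groups)
    return CorrectionPlan(m=m, groups=groups, alpha=alpha)
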