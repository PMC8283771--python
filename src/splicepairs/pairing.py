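"""Base normalization, base-pair geometry classes, and snRNA recognition-loop models.

The central idea: when an snRNA loop (or the homologous Group IIA intron Id3
loop) base-pairs a splice-site sequence, every base pair falls into one of
three geometric categories.

* ``watson_crick`` — the canonical G=C/C=G and A-U/U-A pairs.
* ``isosteric`` — mismatches that can adopt Watson–Crick-like geometry via
  tautomerization or protonation: G-U/U-G, U-U, C-U/U-C, A-C/C-A.
* ``non_isosteric`` — pairs that cannot mimic Watson–Crick geometry and
  perturb the helix: A·G/G·A, A·A, G·G, C·C.

These three sets partition all 16 ordered base pairs (4 + 7 + 5).

Loop models carry the residue identities of the recognition element
(U5 Loop1, the U6 ACAGAGA box, the U1 5' end, or the LtrB Id3 loop) and a
pairing map from signed substrate positions (exon -8..-1, exon +1..+3,
intron +5..+10, ...) to loop residue numbers.  Post-transcriptional
modifications (pseudouridine, 2'-O-methyl, N6-methyl) are annotation only:
pairing geometry is always computed on the parent base.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import yaml

__all__ = [
    "Base",
    "PairClass",
    "LoopModel",
    "PairObservation",
    "canonical_base",
    "normalize_sequence",
    "classify_pair",
    "pair_profile",
    "u5_loop1",
    "u6_acagaga",
    "u1_5prime",
    "ltrb_id3",
    "default_loop_model",
    "parse_position",
    "format_position",
]

# Modified-residue symbols accepted in loop definitions, mapped to parent bases.
# Keys are matched case-sensitively first, then upper-cased.
_MODIFIED = {
    "Ψ": "U",  # pseudouridine
    "PSI": "U",
    "AM": "A", "CM": "C", "GM": "G", "UM": "U", "TM": "U",  # 2'-O-methyl
    "AM6": "A",   # N6-methyladenosine
    "AM6M": "A",  # 2'-O-methyl,N6-methyladenosine
    "GM2": "G",   # N2-methylguanosine
}

_PLAIN = {"A": "A", "C": "C", "G": "G", "U": "U", "T": "U"}


class PairClass(enum.Enum):
    """Geometric class of an RNA:RNA base pair."""

    WATSON_CRICK = "watson_crick"
    ISOSTERIC = "isosteric"
    NON_ISOSTERIC = "non_isosteric"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: unordered pair sets defining the partition of the 16 ordered pairs
_WC = {frozenset(p) for p in (("G", "C"), ("A", "U"))}
_ISO = {frozenset(p) for p in (("G", "U"), ("U", "U"), ("C", "U"), ("A", "C"))}
_NONISO = {frozenset(p) for p in (("A", "G"), ("A", "A"), ("G", "G"), ("C", "C"))}


@dataclass(frozen=True)
class Base:
    """A normalized RNA base together with the raw symbol it came from."""

    code: str
    raw_code: str

    def __post_init__(self) -> None:
        if self.code not in "ACGU":
            raise ValueError(f"internal error: unnormalized base code {self.code!r}")


def canonical_base(raw_code: str, position: object | None = None) -> Base:
    """Normalize a residue symbol to its parent RNA base.

    ``T`` maps to ``U``; pseudouridine and methylation-annotated symbols
    (``Ψ``, ``Gm``, ``Am6`` ...) map to their parent base.  Anything else is
    rejected, naming the offending symbol (and ``position`` if given).
    """
    key = raw_code.strip()
    code = _PLAIN.get(key.upper()) or _MODIFIED.get(key) or _MODIFIED.get(key.upper())
    if code is None:
        where = "" if position is None else f" at position {position}"
        raise ValueError(f"unknown residue symbol {raw_code!r}{where}")
    return Base(code=code, raw_code=raw_code)


def normalize_sequence(seq: str) -> str:
    """Normalize a DNA/RNA string (any case) to uppercase RNA.

    Unknown characters are rejected with their 1-based offset.
    """
    out = []
    for i, ch in enumerate(seq, start=1):
        up = ch.upper()
        if up not in _PLAIN:
            raise ValueError(f"unknown residue symbol {ch!r} at position {i}")
        out.append(_PLAIN[up])
    return "".join(out)


def classify_pair(b1: Base | str, b2: Base | str) -> PairClass:
    """Classify an (unordered) base pair into its geometric category.

    Accepts :class:`Base` objects or raw symbols (normalized on the fly).
    Symmetric and total over the 16 ordered pairs.
    """
    c1 = b1.code if isinstance(b1, Base) else canonical_base(b1).code
    c2 = b2.code if isinstance(b2, Base) else canonical_base(b2).code
    key = frozenset((c1, c2))
    if key in _WC:
        return PairClass.WATSON_CRICK
    if key in _ISO:
        return PairClass.ISOSTERIC
    assert key in _NONISO
    return PairClass.NON_ISOSTERIC


# ---------------------------------------------------------------------------
# substrate position labels
# ---------------------------------------------------------------------------

def parse_position(label: str) -> tuple[str, int]:
    """Parse a substrate position label like ``"exon:-1"`` or ``"intron:+5"``.

    Returns ``(side, offset)`` where side is ``"exon"`` or ``"intron"`` and
    offset is the signed position (negative upstream of the boundary).
    """
    side, _, off = label.partition(":")
    side = side.strip().lower()
    if side not in ("exon", "intron") or not off:
        raise ValueError(f"bad position label {label!r}; expected 'exon:-1' style")
    return side, int(off)


def format_position(side: str, offset: int) -> str:
    return f"{side}:{offset:+d}"


@dataclass
class LoopModel:
    """An snRNA (or Id3) recognition element.

    Parameters
    ----------
    name
        Identifier, e.g. ``"U5_loop1"``.
    residues
        Mapping loop position number -> residue symbol (modified symbols
        allowed; geometry uses the parent base).
    pairing_map
        Mapping substrate position label (``"exon:-1"`` style) -> loop
        position number.
    """

    name: str
    residues: dict[int, str]
    pairing_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._bases = {pos: canonical_base(sym, position=pos)
                       for pos, sym in self.residues.items()}
        for label, loop_pos in self.pairing_map.items():
            parse_position(label)
            if loop_pos not in self.residues:
                raise ValueError(
                    f"pairing map entry {label!r} -> {loop_pos} references a "
                    f"loop position absent from {self.name}"
                )

    def base_at(self, loop_pos: int) -> Base:
        return self._bases[loop_pos]

    def partner_base(self, label: str) -> Base:
        """The loop base paired with substrate position ``label``."""
        return self._bases[self.pairing_map[label]]

    @property
    def ordered_labels(self) -> list[str]:
        """Substrate labels of the pairing map in substrate 5'->3' order.

        Exon upstream positions (negative) come first in ascending order,
        then downstream/intron positive positions ascending.  For maps that
        mix intron and exon sides (U1), intron positions sort after the
        upstream exon block.
        """
        def keyfun(label: str) -> tuple[int, int]:
            side, off = parse_position(label)
            if off < 0:
                return (0, off)
            # downstream of the boundary: exon +N (3' exon) or intron +N
            return (1, off)

        return sorted(self.pairing_map, key=keyfun)

    @property
    def loop_sequence(self) -> str:
        """Loop residues as parent bases, in ascending position order."""
        return "".join(self._bases[p].code for p in sorted(self._bases))

    def uracil_partner_labels(self) -> list[str]:
        """Substrate labels whose loop partner normalizes to U.

        At these positions a non-isosteric pair is impossible: uracil forms
        Watson–Crick or isosteric pairs with every base.
        """
        return [lab for lab in self.ordered_labels
                if self.partner_base(lab).code == "U"]

    # -- serialization ------------------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "name": self.name,
            "residues": {int(k): v for k, v in self.residues.items()},
            "pairing_map": dict(self.pairing_map),
        }
        return yaml.safe_dump(doc, sort_keys=True, allow_unicode=True)

    @classmethod
    def from_yaml(cls, text: str) -> "LoopModel":
        doc = yaml.safe_load(text)
        return cls(
            name=doc["name"],
            residues={int(k): str(v) for k, v in doc["residues"].items()},
            pairing_map={str(k): int(v) for k, v in doc["pairing_map"].items()},
        )


@dataclass(frozen=True)
class PairObservation:
    """One substrate:loop base pair and its geometry class."""

    substrate_position: str
    substrate_base: Base
    loop_position: int
    loop_base: Base
    pair_class: PairClass


def pair_profile(substrate: dict[str, str], model: LoopModel) -> list[PairObservation]:
    """Pair a substrate against a loop model, position by position.

    Parameters
    ----------
    substrate
        Mapping substrate position label -> residue symbol.  Must cover every
        label in the model's pairing map.

    Returns
    -------
    One :class:`PairObservation` per mapped position, in substrate 5'->3'
    order.
    """
    obs = []
    for label in model.ordered_labels:
        if label not in substrate:
            raise ValueError(
                f"substrate does not cover position {label} required by "
                f"loop model {model.name}"
            )
        sub = canonical_base(substrate[label], position=label)
        loop_pos = model.pairing_map[label]
        loop = model.base_at(loop_pos)
        obs.append(PairObservation(
            substrate_position=label,
            substrate_base=sub,
            loop_position=loop_pos,
            loop_base=loop,
            pair_class=classify_pair(sub, loop),
        ))
    return obs


# ---------------------------------------------------------------------------
# reference loop models
# ---------------------------------------------------------------------------

def u5_loop1() -> LoopModel:
    """The invariant 11-nt U5 snRNA Loop1, positions 36–46.

    Residues: C36, Gm37, C38, C39, U40, Um41, U42, Ψ43, U44, A45, C46.
    Five of the eleven normalize to uracil (positions 40–44).  Positions 45
    and 46 are not printed machine-readably in the primary literature text;
    A45/C46 are the internally consistent reconstruction (they keep exactly
    five uracils and complete the 8+3 register) and can be overridden via a
    YAML model file.

    Pairing map (the proposed binding register, 8+3): the exon junction sits
    at C39|C38, so exon -1..-8 pair loop 39..46 and exon +1..+3 pair loop
    38..36.
    """
    residues = {36: "C", 37: "Gm", 38: "C", 39: "C", 40: "U", 41: "Um",
                42: "U", 43: "Ψ", 44: "U", 45: "A", 46: "C"}
    pairing = {format_position("exon", -k): 38 + k for k in range(1, 9)}
    pairing.update({format_position("exon", +k): 39 - k for k in range(1, 4)})
    return LoopModel(name="U5_loop1", residues=residues, pairing_map=pairing)


def u6_acagaga() -> LoopModel:
    """The U6 snRNA ACAGAGA-box region, positions 37–47 (5'->3' C,G,A,U,A,C,A,G,A,G,A).

    Pairing map: intron +5..+10 pair U6 42..37, placing the conserved intron
    +5G against U6 C42.
    """
    seq = "CGAUACAGAGA"  # positions 37..47
    residues = {37 + i: seq[i] for i in range(11)}
    pairing = {format_position("intron", +k): 47 - k for k in range(5, 11)}
    return LoopModel(name="U6_acagaga", residues=residues, pairing_map=pairing)


def u1_5prime() -> LoopModel:
    """The U1 snRNA 5' end, positions 1–11 (A,U,A,C,Ψ,Ψ,A,C,C,U,G).

    Pairing map of the early spliceosome: exon -3..-1 pair U1 11..9 and
    intron +1..+8 pair U1 8..1.
    """
    seq = ["A", "U", "A", "C", "Ψ", "Ψ", "A", "C", "C", "U", "G"]
    residues = {i + 1: seq[i] for i in range(11)}
    pairing = {format_position("exon", -k): 8 + k for k in range(1, 4)}
    pairing.update({format_position("intron", +k): 9 - k for k in range(1, 9)})
    return LoopModel(name="U1_5prime", residues=residues, pairing_map=pairing)


def ltrb_id3() -> LoopModel:
    """The Ll.LtrB Group IIA intron Id3 loop, positions 275–285 (synthetic default).

    The exact loop sequence is not available as machine-readable text; this
    default is a synthetic reconstruction constrained by the published
    interaction pattern: guanines at 278/279 coordinate the splice junction
    via C=G pairs, G282 forms the U(-4)--G homing-site pair, and five of the
    eleven residues are uracils, as in U5 Loop1.  Override with a YAML model
    for real analyses.

    Pairing map (7+4 register): EBS1 (positions 279–285) pairs exon -1..-7;
    delta (positions 275–278) pairs exon +1..+4.
    """
    seq = ["A", "U", "U", "G", "G", "U", "U", "G", "U", "A", "C"]  # 275..285
    residues = {275 + i: seq[i] for i in range(11)}
    pairing = {format_position("exon", -k): 278 + k for k in range(1, 8)}
    pairing.update({format_position("exon", +k): 279 - k for k in range(1, 5)})
    return LoopModel(name="LtrB_Id3", residues=residues, pairing_map=pairing)


_FACTORIES = {
    "U5_loop1": u5_loop1,
    "U6_acagaga": u6_acagaga,
    "U1_5prime": u1_5prime,
    "LtrB_Id3": ltrb_id3,
}


def default_loop_model(name: str) -> LoopModel:
    """Look up a built-in loop model by name."""
    try:
        return _FACTORIES[name]()
    except KeyError:
        raise ValueError(
            f"unknown loop model {name!r}; available: {sorted(_FACTORIES)}"
        ) from None
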