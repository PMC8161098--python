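"""Compound and protein descriptor vectors.

The interaction model consumes a concatenation of a compound block and a
protein block. The compound block is a hashed circular-substructure
(Morgan) count fingerprint plus a short physicochemical tail; the protein
block is the classical sequence-descriptor triple AAC + DPC + CTD
(amino-acid composition, dipeptide composition, and per-property
composition/transition/distribution).

Every descriptor carries a ``schema_id`` so that models can refuse
vectors computed under a different configuration. Both descriptor kinds
are fully deterministic functions of their input.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit.Chem import Descriptors, rdFingerprintGenerator, rdMolDescriptors

from .chem_io import STANDARD_AA, Compound, ProteinTarget

AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}

#: distribution quantiles reported per CTD group, in order
CTD_QUANTILES = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class DescriptorVector:
    owner_id: str
    kind: str  # "compound" | "protein"
    values: np.ndarray
    schema_id: str

    def __post_init__(self) -> None:
        if self.kind not in ("compound", "protein"):
            raise ValueError(f"kind must be compound|protein, got {self.kind!r}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.owner_id}: non-finite descriptor values")


@dataclass(frozen=True)
class PropertyGrouping:
    """A partition of the 20 amino acids into 3 disjoint classes."""

    name: str
    groups: tuple[tuple[str, str], ...]  # ((group_name, letters), ...) x3

    def __post_init__(self) -> None:
        if len(self.groups) != 3:
            raise ValueError(f"{self.name}: need exactly 3 classes")
        letters = "".join(g for _, g in self.groups)
        if sorted(letters) != sorted(STANDARD_AA):
            raise ValueError(
                f"{self.name}: classes must partition the 20 standard letters"
            )

    def class_of(self) -> dict[str, int]:
        """Map each amino-acid letter to its class index 0/1/2."""
        return {ch: gi for gi, (_, letters) in enumerate(self.groups) for ch in letters}


def load_groupings(path: str | Path | None = None) -> list[PropertyGrouping]:
    """Load CTD property groupings from a TSV (property, group, letters).

    Defaults to the packaged table of seven classical properties:
    hydrophobicity, van der Waals volume, polarity, polarizability,
    charge, secondary-structure propensity and solvent accessibility.
    """
    if path is None:
        src = importlib.resources.files("cgbscreen.data").joinpath("ctd_groups.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    by_prop: dict[str, list[tuple[str, str]]] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:  # skip header
        prop, group, letters = ln.split("\t")
        by_prop.setdefault(prop, []).append((group, letters))
    return [PropertyGrouping(name, tuple(groups)) for name, groups in by_prop.items()]


DEFAULT_GROUPINGS = load_groupings()


# ---------------------------------------------------------------------------
# compound descriptors

# (name, function, scale): each physchem feature is divided by its scale
# and clipped to [0, 1] so the SVM sees bounded inputs.
_PHYSCHEM = (
    ("mol_weight", Descriptors.MolWt, 1000.0),
    ("heavy_atoms", lambda m: m.GetNumHeavyAtoms(), 100.0),
    ("ring_count", rdMolDescriptors.CalcNumRings, 10.0),
    ("hbd", rdMolDescriptors.CalcNumHBD, 10.0),
    ("hba", rdMolDescriptors.CalcNumHBA, 20.0),
    ("frac_aromatic", None, 1.0),  # computed inline, already in [0, 1]
)


@dataclass(frozen=True)
class CompoundSchema:
    """Configuration of the compound descriptor block."""

    radius: int = 2
    n_bits: int = 1024
    physchem: bool = True

    @property
    def schema_id(self) -> str:
        pc = "+physchem6" if self.physchem else ""
        return f"cmpd/morgan_r{self.radius}_{self.n_bits}c{pc}/v1"

    @property
    def length(self) -> int:
        return self.n_bits + (6 if self.physchem else 0)


_FP_GENERATORS: dict[tuple[int, int], object] = {}


def _fp_generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _FP_GENERATORS:
        _FP_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _FP_GENERATORS[key]


def compound_descriptor(c: Compound, schema: CompoundSchema | None = None) -> DescriptorVector:
    """Hashed Morgan count fingerprint plus scaled physicochemical tail."""
    schema = schema or CompoundSchema()
    mol = c.mol()
    gen = _fp_generator(schema.radius, schema.n_bits)
    counts = gen.GetCountFingerprintAsNumPy(mol).astype(float)
    blocks = [counts]
    if schema.physchem:
        n_heavy = mol.GetNumHeavyAtoms()
        frac_arom = (
            sum(a.GetIsAromatic() for a in mol.GetAtoms()) / n_heavy if n_heavy else 0.0
        )
        pc = []
        for name, fn, scale in _PHYSCHEM:
            raw = frac_arom if fn is None else fn(mol)
            pc.append(min(max(raw / scale, 0.0), 1.0))
        blocks.append(np.asarray(pc))
    return DescriptorVector(c.id, "compound", np.concatenate(blocks), schema.schema_id)


# ---------------------------------------------------------------------------
# protein descriptors


def aac(seq: str) -> np.ndarray:
    """Amino-acid composition: count(a)/N for each of the 20 letters."""
    if not seq:
        raise ValueError("empty sequence")
    v = np.zeros(20)
    for ch in seq:
        v[AA_INDEX[ch]] += 1
    return v / len(seq)


def dpc(seq: str) -> np.ndarray:
    """Dipeptide composition: count(ab)/(N-1) over overlapping dipeptides."""
    if len(seq) < 2:
        raise ValueError("dipeptide composition needs length >= 2")
    v = np.zeros(400)
    for a, b in zip(seq, seq[1:]):
        v[AA_INDEX[a] * 20 + AA_INDEX[b]] += 1
    return v / (len(seq) - 1)


def ctd(seq: str, groupings: list[PropertyGrouping] | None = None) -> np.ndarray:
    """Composition / transition / distribution descriptor.

    For each property the sequence is recoded into 3 classes, then:

    * composition — fraction of positions in each class (3 values);
    * transition — frequency of adjacent unordered class pairs,
      (count(gh) + count(hg)) / (N-1), pairs (0,1), (0,2), (1,2);
    * distribution — for each class, the 1-based position of its first,
      25th-, 50th-, 75th-percentile and last occurrence divided by N
      (the q-quantile is the ceil(q * n_g)-th occurrence); an absent
      class reports 0 for all five.

    21 values per property; the 7 default properties give 147.
    """
    groupings = groupings if groupings is not None else DEFAULT_GROUPINGS
    if not groupings:
        raise ValueError("at least one property grouping is required")
    n = len(seq)
    if n < 30:
        raise ValueError(f"CTD needs sequence length >= 30, got {n}")

    out: list[float] = []
    for grouping in groupings:
        cls = grouping.class_of()
        codes = np.fromiter((cls[ch] for ch in seq), dtype=np.int8, count=n)
        # composition
        comp = np.bincount(codes, minlength=3) / n
        out.extend(comp)
        # transition
        a, b = codes[:-1], codes[1:]
        for g, h in ((0, 1), (0, 2), (1, 2)):
            out.append(np.count_nonzero((a == g) & (b == h) | (a == h) & (b == g)) / (n - 1))
        # distribution
        for g in range(3):
            pos = np.flatnonzero(codes == g) + 1  # 1-based positions
            if pos.size == 0:
                out.extend([0.0] * len(CTD_QUANTILES))
                continue
            for q in CTD_QUANTILES:
                k = max(1, int(np.ceil(q * pos.size)))
                out.append(pos[k - 1] / n)
    return np.asarray(out)


@dataclass(frozen=True)
class ProteinSchema:
    """Configuration of the protein descriptor block (AAC + DPC + CTD)."""

    use_aac: bool = True
    use_dpc: bool = True
    use_ctd: bool = True
    groupings: tuple[PropertyGrouping, ...] = field(
        default_factory=lambda: tuple(DEFAULT_GROUPINGS)
    )

    @property
    def schema_id(self) -> str:
        blocks = [
            name
            for name, on in (("aac", self.use_aac), ("dpc", self.use_dpc), ("ctd", self.use_ctd))
            if on
        ]
        props = ",".join(g.name for g in self.groupings) if self.use_ctd else "-"
        return f"prot/{'+'.join(blocks)}/{props}/v1"

    @property
    def length(self) -> int:
        return (
            (20 if self.use_aac else 0)
            + (400 if self.use_dpc else 0)
            + (21 * len(self.groupings) if self.use_ctd else 0)
        )


def protein_descriptor(t: ProteinTarget, schema: ProteinSchema | None = None) -> DescriptorVector:
    """Concatenated AAC + DPC + CTD vector (default length 20+400+147 = 567)."""
    schema = schema or ProteinSchema()
    blocks = []
    if schema.use_aac:
        blocks.append(aac(t.sequence))
    if schema.use_dpc:
        blocks.append(dpc(t.sequence))
    if schema.use_ctd:
        blocks.append(ctd(t.sequence, list(schema.groupings)))
    return DescriptorVector(t.id, "protein", np.concatenate(blocks), schema.schema_id)
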