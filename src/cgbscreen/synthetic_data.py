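"""Fully in-silico chemogenomic universe with planted binding structure.

The generator emulates a curated bioactivity corpus: a compound library
assembled from a scaffold x substituent grammar, protein targets drawn
as mutated copies of family archetype sequences, and a latent binding
rule per target. A compound truly binds a target when it carries at
least ``rule_threshold`` distinct substituents from the target's
preferred substituent set; observed labels are the true labels flipped
with probability ``noise_rate``.

Because the rule lives on substituents and not on scaffolds, actives on
a new scaffold exist by construction — the statistical structure that
scaffold-hopping retrieval assumes. Compounds are real parseable
molecules so the genuine descriptor pipeline is exercised end to end,
and everything is bit-reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem_io import STANDARD_AA, Compound, CPIRecord, ProteinTarget
from .cpi_model import sample_negative_pairs

logger = logging.getLogger(__name__)

#: ring-system templates; each has three substitution slots filled with
#: branch SMILES or [H]
SCAFFOLDS: dict[str, str] = {
    "benzene": "c1cc({0})c({1})cc1{2}",
    "pyridine": "c1cc({0})nc({1})c1{2}",
    "pyrimidine": "c1nc({0})nc({1})c1{2}",
    "thiophene": "c1sc({0})c({1})c1{2}",
    "furan": "c1oc({0})c({1})c1{2}",
    "pyrrole": "c1[nH]c({0})c({1})c1{2}",
    "cyclohexane": "C1CC({0})C({1})CC1{2}",
    "naphthalene": "c1ccc2cc({0})c({1})cc2c1{2}",
}

#: substituent fragments (branch SMILES); the binding rules select
#: preferred subsets of these
SUBSTITUENTS: tuple[str, ...] = (
    "F",
    "Cl",
    "Br",
    "C",
    "O",
    "OC",
    "N",
    "C#N",
    "C(F)(F)F",
    "C(=O)O",
    "C(=O)OC",
    "C(=O)N",
    "S(=O)(=O)N",
    "CC",
    "OCC",
    "NC(C)=O",
)


@dataclass
class SyntheticUniverse:
    compounds: list[Compound]
    targets: list[ProteinTarget]
    scaffold_of: dict[str, str]  # compound id -> scaffold name
    substituents_of: dict[str, tuple[int, ...]]  # compound id -> substituent indices
    rules: dict[str, frozenset[int]]  # target id -> preferred substituent indices
    rule_threshold: int
    truth: np.ndarray = field(repr=False)  # (n_compounds, n_targets) noiseless labels
    observed: np.ndarray = field(repr=False)  # truth with noise flips applied
    noise_rate: float = 0.0
    seed: int = 0

    def compound_index(self) -> dict[str, int]:
        return {c.id: i for i, c in enumerate(self.compounds)}

    def target_index(self) -> dict[str, int]:
        return {t.id: i for i, t in enumerate(self.targets)}

    def true_label(self, compound_id: str, target_id: str) -> int:
        return int(self.truth[self.compound_index()[compound_id],
                              self.target_index()[target_id]])


def binds_rule(
    substituents: Sequence[int], preferred: frozenset[int], threshold: int
) -> bool:
    """True binding iff >= threshold *distinct* preferred substituents."""
    return len(set(substituents) & preferred) >= threshold


def _assemble_smiles(scaffold: str, slot_subs: Sequence[str | None]) -> str:
    filled = [s if s is not None else "[H]" for s in slot_subs]
    return SCAFFOLDS[scaffold].format(*filled)


def make_compound(
    cid: str, scaffold: str, sub_indices: Sequence[int], rng: np.random.Generator
) -> Compound:
    """Assemble a compound from a scaffold and substituent indices."""
    if len(sub_indices) > 3:
        raise ValueError("at most 3 substituent slots per scaffold")
    slots: list[str | None] = [None, None, None]
    positions = rng.permutation(3)[: len(sub_indices)]
    for pos, si in zip(positions, sub_indices):
        slots[pos] = SUBSTITUENTS[si]
    smiles = _assemble_smiles(scaffold, slots)
    return Compound.from_smiles(cid, smiles)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(STANDARD_AA), size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    letters = list(seq)
    for i in range(len(letters)):
        if rng.random() < rate:
            letters[i] = STANDARD_AA[int(rng.integers(0, 20))]
    return "".join(letters)


def generate_universe(
    n_targets: int = 20,
    n_compounds: int = 2000,
    n_scaffolds: int = 8,
    family_count: int = 4,
    noise_rate: float = 0.05,
    seed: int = 0,
    preferred_set_size: int = 5,
    rule_threshold: int = 2,
    min_binders: int = 160,
    seq_length: int = 300,
    mutation_rate: float = 0.2,
    sub_count_weights: tuple[float, float, float] = (0.20, 0.45, 0.35),
) -> SyntheticUniverse:
    """Generate a reproducible chemogenomic universe with planted rules.

    Each target's preferred substituent set is redrawn (up to a retry
    budget) until the library contains at least ``min_binders`` true
    binders for it, so every target can support both model training and
    the panel filter. Raises ``ValueError`` when the parameters make
    that infeasible.
    """
    if not 0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must be in [0, 0.5)")
    if n_scaffolds < 2 or n_scaffolds > len(SCAFFOLDS):
        raise ValueError(f"n_scaffolds must be in [2, {len(SCAFFOLDS)}]")
    if rule_threshold < 0 or preferred_set_size < rule_threshold:
        raise ValueError("need preferred_set_size >= rule_threshold >= 0")
    if min_binders > n_compounds:
        raise ValueError("min_binders cannot exceed n_compounds")

    rng = np.random.default_rng(seed)
    scaffold_names = list(SCAFFOLDS)[:n_scaffolds]

    # compounds
    compounds: list[Compound] = []
    scaffold_of: dict[str, str] = {}
    substituents_of: dict[str, tuple[int, ...]] = {}
    width = len(str(n_compounds))
    for k in range(n_compounds):
        cid = f"C{k + 1:0{width}d}"
        scaffold = scaffold_names[int(rng.integers(0, n_scaffolds))]
        n_subs = 1 + int(rng.choice(3, p=sub_count_weights))
        subs = tuple(int(s) for s in rng.choice(len(SUBSTITUENTS), size=n_subs, replace=False))
        compounds.append(make_compound(cid, scaffold, subs, rng))
        scaffold_of[cid] = scaffold
        substituents_of[cid] = subs

    # targets: family archetypes mutated per member
    archetypes = [_random_sequence(seq_length, rng) for _ in range(family_count)]
    targets: list[ProteinTarget] = []
    twidth = len(str(n_targets))
    for k in range(n_targets):
        tid = f"T{k + 1:0{twidth}d}"
        seq = _mutate(archetypes[k % family_count], mutation_rate, rng)
        targets.append(ProteinTarget(id=tid, sequence=seq))

    # latent rules with a feasibility retry budget per target
    sub_sets = [set(substituents_of[c.id]) for c in compounds]
    rules: dict[str, frozenset[int]] = {}
    truth = np.zeros((n_compounds, n_targets), dtype=np.int8)
    for j, t in enumerate(targets):
        ok = False
        for _ in range(500):
            preferred = frozenset(
                int(s)
                for s in rng.choice(len(SUBSTITUENTS), size=preferred_set_size, replace=False)
            )
            labels = np.fromiter(
                (len(s & preferred) >= rule_threshold for s in sub_sets),
                dtype=np.int8,
                count=n_compounds,
            )
            if labels.sum() >= min_binders:
                rules[t.id] = preferred
                truth[:, j] = labels
                ok = True
                break
        if not ok:
            raise ValueError(
                f"infeasible parameters: no rule for {t.id} reaches "
                f"{min_binders} true binders in a {n_compounds}-compound library"
            )

    flips = rng.random(truth.shape) < noise_rate
    observed = np.where(flips, 1 - truth, truth).astype(np.int8)

    logger.info(
        "universe: %d compounds, %d targets, binders/target %s (median %d)",
        n_compounds,
        n_targets,
        truth.sum(axis=0).tolist(),
        int(np.median(truth.sum(axis=0))),
    )
    return SyntheticUniverse(
        compounds=compounds,
        targets=targets,
        scaffold_of=scaffold_of,
        substituents_of=substituents_of,
        rules=rules,
        rule_threshold=rule_threshold,
        truth=truth,
        observed=observed,
        noise_rate=noise_rate,
        seed=seed,
    )


def emit_training_set(
    u: SyntheticUniverse,
    holdout_fraction: float = 0.25,
    seed: int = 0,
    negative_ratio: float = 1.0,
    max_pos_per_target: int | None = 120,
) -> tuple[list[CPIRecord], list[CPIRecord]]:
    """Compound-disjoint train/test split of the observed labels.

    ``round(holdout_fraction * n_compounds)`` compounds are held out; no
    held-out compound contributes any training pair. Training records
    are the observed-positive pairs of training compounds (optionally
    capped per target to bound SVM cost) plus uniformly sampled
    non-positive pairs at ``negative_ratio`` negatives per kept
    positive. Test records cover every (held-out compound, target) pair
    with its observed label.
    """
    if not 0 <= holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in [0, 1)")
    rng = np.random.default_rng([seed, 0x51])  # domain-separated from the universe stream
    n = len(u.compounds)
    n_test = round(holdout_fraction * n)
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train_idx = [i for i in range(n) if i not in test_idx]

    cidx = {i: c.id for i, c in enumerate(u.compounds)}

    # observed positives among training compounds, grouped per target
    all_train_pos: list[CPIRecord] = []
    kept_pos: list[CPIRecord] = []
    for j, t in enumerate(u.targets):
        pos_i = [i for i in train_idx if u.observed[i, j] == 1]
        recs = [CPIRecord(cidx[i], t.id, 1) for i in pos_i]
        all_train_pos.extend(recs)
        if max_pos_per_target is not None and len(recs) > max_pos_per_target:
            picks = rng.choice(len(recs), size=max_pos_per_target, replace=False)
            recs = [recs[k] for k in sorted(picks)]
        kept_pos.extend(recs)

    train_compounds = [u.compounds[i] for i in train_idx]
    if kept_pos:
        # exclude every observed-positive train pair, not just the kept ones
        ratio = negative_ratio * len(kept_pos) / len(all_train_pos)
        negatives = sample_negative_pairs(
            all_train_pos,
            train_compounds,
            u.targets,
            ratio=ratio,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    else:
        negatives = []

    train_records = kept_pos + negatives
    test_records = [
        CPIRecord(cidx[i], t.id, int(u.observed[i, j]))
        for i in sorted(test_idx)
        for j, t in enumerate(u.targets)
    ]
    return train_records, test_records


@dataclass
class ScaffoldHopBenchmark:
    """A screening library with planted scaffold-hopped actives.

    ``references`` are known binders of the reference target, all on one
    scaffold. The library mixes (i) "hops": fresh binders on other
    scaffolds, (ii) "lookalikes": non-binders on the reference scaffold,
    and (iii) random grammar compounds; ``truth_binders`` lists every
    library compound that truly binds the reference target under the
    universe's noiseless rule.
    """

    reference_target_id: str
    reference_scaffold: str
    references: list[Compound]
    library: list[Compound]
    truth_binders: set[str]
    roles: dict[str, str]  # library id -> hop | lookalike | decoy
    scaffold_of: dict[str, str]


def make_scaffold_hop_benchmark(
    u: SyntheticUniverse,
    reference_target_id: str | None = None,
    seed: int = 0,
    library_size: int = 5000,
    n_hops: int = 50,
    n_lookalikes: int = 150,
    n_references: int = 20,
) -> ScaffoldHopBenchmark:
    """Build a reference set and screening library for hop retrieval."""
    # domain-separated stream: the same seed as generate_universe must not
    # replay the universe's compound draws into the library
    rng = np.random.default_rng([seed, 0x5C])
    tix = u.target_index()
    if reference_target_id is None:
        reference_target_id = max(
            (t.id for t in u.targets), key=lambda tid: int(u.truth[:, tix[tid]].sum())
        )
    j = tix[reference_target_id]
    preferred = u.rules[reference_target_id]
    binder_ids = [c.id for i, c in enumerate(u.compounds) if u.truth[i, j] == 1]
    if not binder_ids:
        raise ValueError(f"{reference_target_id} has no true binders")

    # modal scaffold among the target's binders becomes the reference scaffold
    counts: dict[str, int] = {}
    for cid in binder_ids:
        counts[u.scaffold_of[cid]] = counts.get(u.scaffold_of[cid], 0) + 1
    ref_scaffold = max(sorted(counts), key=lambda s: counts[s])
    same_scaffold_binders = [cid for cid in binder_ids if u.scaffold_of[cid] == ref_scaffold]
    if len(same_scaffold_binders) < n_references:
        raise ValueError(
            f"only {len(same_scaffold_binders)} binders on scaffold "
            f"{ref_scaffold}; cannot draw {n_references} references"
        )
    picks = rng.choice(len(same_scaffold_binders), size=n_references, replace=False)
    by_id = {c.id: c for c in u.compounds}
    references = [by_id[same_scaffold_binders[k]] for k in sorted(picks)]

    scaffold_names = sorted({u.scaffold_of[c.id] for c in u.compounds})
    other_scaffolds = [s for s in scaffold_names if s != ref_scaffold]
    non_preferred = [k for k in range(len(SUBSTITUENTS)) if k not in preferred]
    pref_list = sorted(preferred)
    thr = u.rule_threshold

    library: list[Compound] = []
    roles: dict[str, str] = {}
    scaffold_of: dict[str, str] = {}
    subs_of: dict[str, tuple[int, ...]] = {}
    width = len(str(library_size))

    def add(cid: str, scaf: str, subs: Sequence[int], role: str) -> None:
        compound = make_compound(cid, scaf, subs, rng)
        library.append(compound)
        roles[compound.id] = role
        scaffold_of[compound.id] = scaf
        subs_of[compound.id] = tuple(subs)

    k = 0

    def next_id() -> str:
        nonlocal k
        k += 1
        return f"L{k:0{width}d}"

    # (i) planted hops: binders by rule, never on the reference scaffold
    for _ in range(n_hops):
        scaf = other_scaffolds[int(rng.integers(0, len(other_scaffolds)))]
        n_pref = int(rng.integers(thr, min(len(pref_list), 3) + 1))
        subs = [int(s) for s in rng.choice(pref_list, size=n_pref, replace=False)]
        if n_pref < 3 and rng.random() < 0.5:
            subs.append(int(rng.choice(non_preferred)))
        add(next_id(), scaf, subs, "hop")

    # (ii) decoy lookalikes: reference scaffold, too few preferred substituents
    for _ in range(n_lookalikes):
        n_subs = 1 + int(rng.choice(3, p=(0.2, 0.45, 0.35)))
        n_pref = min(int(rng.integers(0, thr)), n_subs)
        subs = [int(s) for s in rng.choice(pref_list, size=n_pref, replace=False)]
        subs += [
            int(s) for s in rng.choice(non_preferred, size=n_subs - n_pref, replace=False)
        ]
        add(next_id(), ref_scaffold, subs, "lookalike")

    # (iii) random grammar compounds; whatever the rule says is the truth
    while len(library) < library_size:
        scaf = scaffold_names[int(rng.integers(0, len(scaffold_names)))]
        n_subs = 1 + int(rng.choice(3, p=(0.2, 0.45, 0.35)))
        subs = [int(s) for s in rng.choice(len(SUBSTITUENTS), size=n_subs, replace=False)]
        add(next_id(), scaf, subs, "decoy")

    truth_binders = {
        cid for cid, subs in subs_of.items() if binds_rule(subs, preferred, thr)
    }
    return ScaffoldHopBenchmark(
        reference_target_id=reference_target_id,
        reference_scaffold=ref_scaffold,
        references=references,
        library=library,
        truth_binders=truth_binders,
        roles=roles,
        scaffold_of=scaffold_of,
    )


def evaluate_hop_screen(
    bench: ScaffoldHopBenchmark,
    hit_ids: Sequence[str],
    radius: int = 2,
    n_bits: int = 2048,
) -> dict:
    """Enrichment and scaffold-hop statistics for a screened hit list.

    Reports the number of true binders among the hits, the one-sided
    hypergeometric p-value against chance retrieval from the library,
    and how many retrieved binders are scaffold hops — binders whose
    maximum Morgan/Tanimoto similarity to every reference falls below
    the median of that quantity over the library's same-scaffold
    (reference-scaffold) compounds.
    """
    from scipy.stats import hypergeom

    from .cgbsp_screen import morgan_fingerprint, tanimoto

    ref_fps = [morgan_fingerprint(r, radius, n_bits) for r in bench.references]

    def max_sim(c: Compound) -> float:
        fp = morgan_fingerprint(c, radius, n_bits)
        return max(tanimoto(fp, rf) for rf in ref_fps)

    by_id = {c.id: c for c in bench.library}
    same_scaffold = [
        c for c in bench.library if bench.scaffold_of[c.id] == bench.reference_scaffold
    ]
    same_scaffold_median = float(np.median([max_sim(c) for c in same_scaffold]))

    retrieved_binders = [cid for cid in hit_ids if cid in bench.truth_binders]
    hop_ids = [
        cid for cid in retrieved_binders if max_sim(by_id[cid]) < same_scaffold_median
    ]

    n, k = len(bench.library), len(bench.truth_binders)
    x = len(retrieved_binders)
    p = float(hypergeom.sf(x - 1, n, k, len(hit_ids)))
    return {
        "n_hits": len(hit_ids),
        "n_true_binders_in_library": k,
        "n_binders_retrieved": x,
        "chance_expectation": len(hit_ids) * k / n,
        "p_hypergeom": p,
        "same_scaffold_median_tanimoto": same_scaffold_median,
        "n_scaffold_hops_retrieved": len(hop_ids),
        "hop_ids": hop_ids,
    }


def write_universe(u: SyntheticUniverse, out_dir) -> None:
    """Write library.smi, targets.fasta, cpi.tsv (observed) and truth.tsv."""
    from pathlib import Path

    from .chem_io import write_cpi_table, write_fasta, write_molecules

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_molecules(u.compounds, out / "library.smi")
    write_fasta(u.targets, out / "targets.fasta")
    observed = [
        CPIRecord(c.id, t.id, int(u.observed[i, j]))
        for i, c in enumerate(u.compounds)
        for j, t in enumerate(u.targets)
    ]
    write_cpi_table(observed, out / "cpi.tsv")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("compound_id\ttarget_id\tlabel\n")
        for i, c in enumerate(u.compounds):
            for j, t in enumerate(u.targets):
                fh.write(f"{c.id}\t{t.id}\t{int(u.truth[i, j])}\n")
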