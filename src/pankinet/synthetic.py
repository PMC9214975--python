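"""Synthetic bioactivity corpora and planted-motif compound benchmarks.

Real PKFI curation starts from hundreds of thousands of heterogeneous
compound-kinase measurements (two sources, duplicated and partially
inconsistent records, per-family test coverage ranging from a single
kinase to the whole family). This module fabricates inputs with the same
statistical structure so that every pipeline stage is testable offline:

* **Compounds** are assembled from a library of ~20 drug-like ring
  scaffolds, randomly decorated with small benign substituents. Designated
  positives carry a grafted *family motif* (default: a nitrile — the
  "triple-bonded nitrogen" environment typical of pan-JAK chemistry);
  negatives receive a decoy substituent instead, so the motif is the only
  systematic class difference (a Bayes-sufficient signal). The atom
  indices of every planted motif are recorded in canonical atom order.
* **Activity tables** test each compound on a random subset of its
  family's kinase members, draw IC50/pKi values log-uniformly inside or
  outside the activity cutoffs, inject duplicate records (a fraction of
  which are made inconsistent enough to fail the 80% vote), and sprinkle
  unusable censored-relation records. The generator computes, by direct
  fraction arithmetic independent of the curation code, the consensus
  label the pipeline *should* produce for every compound — the
  ground-truth oracle for end-to-end recovery tests.

One integer seed fans out to per-stage random streams, so every output is
reproducible bit for bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.rdBase import BlockLogs

from .pkfi import ACTIVE, INACTIVE, MIXED, RawActivityRecord, KinaseFamily, PKFISet

logger = logging.getLogger(__name__)

#: Drug-like ring scaffolds (all well under the 50-heavy-atom cap).
SCAFFOLDS = (
    "c1ccccc1", "c1ccncc1", "c1cncnc1", "c1ccc2[nH]ccc2c1",
    "c1ccc2ncccc2c1", "c1ccc2ccccc2c1", "c1ccc2[nH]cnc2c1",
    "c1ccc2occc2c1", "c1ccc2sccc2c1", "c1cc[nH]n1", "c1c[nH]cn1",
    "c1ccsc1", "c1ccoc1", "C1CCNCC1", "C1COCCN1", "C1CNCCN1",
    "C1CCCCC1", "C1CCNC1", "c1ccc2c(c1)ncnc2", "c1ccc(-c2ccccc2)cc1",
    "COc1ccccc1",
)

#: Benign substituents used for decoration and as decoys on negatives.
DECORATIONS = ("C", "CC", "O", "OC", "N", "Cl", "F")

#: Family motifs: nitrile, sulfonamide, trifluoromethyl (cycled).
MOTIFS = ("C#N", "S(=O)(=O)N", "C(F)(F)F")

GROUPS = ("TK", "AGC", "CMGC", "CAMK")

INELIGIBLE = "ineligible"


@dataclass
class SyntheticConfig:
    """Knobs of the generator; the defaults define the benchmark conditions."""

    n_families: int = 3
    members_per_family: int = 4
    n_compounds: int = 800
    pos_fraction: float = 0.5          # designated pan-actives
    motifs: tuple = MOTIFS             # one motif per family, cycled
    motif_prevalence_pos: float = 1.0  # fraction of positives carrying it
    label_noise: float = 0.0           # per-pair consensus flip probability
    duplicate_rate: float = 0.2        # pairs receiving extra records
    inconsistency_rate: float = 0.1    # duplicated pairs made vote-failing
    censored_rate: float = 0.05        # extra '~'/'>>' records per pair
    coverage_min: int = 1              # tested members drawn uniformly
    coverage_max: int | None = None    # ... up to the family size
    seed: int = 0

    def __post_init__(self):
        for name in ("pos_fraction", "motif_prevalence_pos", "label_noise",
                     "duplicate_rate", "inconsistency_rate", "censored_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SyntheticCompound:
    compound_id: str
    smiles: str
    family_id: str
    pan_active: bool       # intended pan-family label
    planted: bool          # actually carries the family motif
    motif_atoms: frozenset = field(default_factory=frozenset)


@dataclass
class Benchmark:
    """A labeled, structure-resolved set with motif ground truth."""

    pkfi_set: PKFISet
    structures: dict       # compound_id -> canonical SMILES
    motif_atoms: dict      # compound_id -> frozenset of atom indices
    motif_smarts: str
    compounds: list


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _graft(mol: Chem.Mol, frag_smiles: str, rng) -> Chem.Mol:
    """Attach a fragment's first atom to a random H-bearing atom."""
    frag = Chem.MolFromSmiles(frag_smiles)
    cand = [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]
    if not cand:
        raise ValueError("no attachable atom on scaffold")
    i = int(rng.choice(cand))
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(i, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return out


def gen_families(config: SyntheticConfig) -> list:
    """Synthetic kinase families FAM1..FAMn with evenly sized membership."""
    families = []
    for f in range(config.n_families):
        fid = f"FAM{f + 1}"
        members = frozenset(f"{fid}_K{k + 1}"
                            for k in range(config.members_per_family))
        families.append(KinaseFamily(
            family_id=fid, group=GROUPS[f % len(GROUPS)],
            member_kinase_ids=members))
    return families


def _build_compound(rng, motif: str | None, motif_query) -> tuple:
    """One decorated scaffold, optionally motif-grafted; retried on failure."""
    for _ in range(30):
        try:
            with BlockLogs():
                mol = Chem.MolFromSmiles(str(rng.choice(SCAFFOLDS)))
                for _ in range(int(rng.integers(0, 3))):
                    mol = _graft(mol, str(rng.choice(DECORATIONS)), rng)
                if motif is not None:
                    mol = _graft(mol, motif, rng)
                else:
                    mol = _graft(mol, str(rng.choice(DECORATIONS)), rng)
                smiles = Chem.MolToSmiles(mol)
                mol = Chem.MolFromSmiles(smiles)
            if mol is None or mol.GetNumAtoms() > 50:
                continue
            matches = mol.GetSubstructMatches(motif_query)
            if motif is not None and not matches:
                continue
            if motif is None and matches:
                continue  # decoy accidentally formed the motif: resample
            atoms = frozenset(i for m in matches for i in m)
            return smiles, atoms
        except (ValueError, Chem.rdchem.KekulizeException,
                Chem.rdchem.AtomValenceException):
            continue
    raise RuntimeError("could not build a valid synthetic compound")


def gen_compounds(config: SyntheticConfig, families=None) -> list:
    """Generate the compound panel: scaffold + decorations (+ motif).

    Compounds are dealt round-robin across families; the first
    ``pos_fraction`` of each family's compounds are designated pan-actives
    and carry the family motif with probability ``motif_prevalence_pos``.
    """
    if families is None:
        families = gen_families(config)
    rng, = _streams(config.seed, 1)
    compounds = []
    for idx in range(config.n_compounds):
        family = families[idx % len(families)]
        motif = config.motifs[(idx % len(families)) % len(config.motifs)]
        query = Chem.MolFromSmarts(motif)
        rank_in_family = idx // len(families)
        per_family = math.ceil(config.n_compounds / len(families))
        pan_active = rank_in_family < config.pos_fraction * per_family
        planted = bool(pan_active and rng.random() < config.motif_prevalence_pos)
        smiles, atoms = _build_compound(rng, motif if planted else None, query)
        compounds.append(SyntheticCompound(
            compound_id=f"CPD{idx + 1:06d}", smiles=smiles,
            family_id=family.family_id, pan_active=pan_active,
            planted=planted, motif_atoms=atoms))
    logger.info("generated %d compounds (%d motif-planted)",
                len(compounds), sum(c.planted for c in compounds))
    return compounds


def _inconsistent_split(total: int) -> int:
    """Minority count making the majority fraction fall strictly below 0.8."""
    frac = 0.8 * total
    majority_max = int(frac) - 1 if frac == int(frac) else int(frac)
    return total - majority_max


def _draw_value(rng, call: str, measure: str) -> float:
    """Log-uniform activity value inside/outside the cutoff for the call."""
    if measure == "IC50_nM":
        lo, hi = (1.0, 499.0) if call == ACTIVE else (501.0, 1e5)
        return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
    lo, hi = (6.01, 10.0) if call == ACTIVE else (3.0, 5.99)
    return float(rng.uniform(lo, hi))


def _make_record(rng, compound, kinase_id, call):
    if rng.random() < 0.5:
        source, measure = "chembl-like", "IC50_nM"
    else:
        source, measure = "profiling-like", "pKi"
    return RawActivityRecord(
        compound_id=compound.compound_id, smiles=compound.smiles,
        kinase_id=kinase_id, measure=measure, relation="=",
        value=_draw_value(rng, call, measure), source=source)


def gen_activity_table(config: SyntheticConfig, compounds=None, families=None):
    """Raw activity records plus the generator-side ground truth.

    Returns ``(records, truth)`` where ``truth[family_id][compound_id]``
    is the consensus outcome — active/inactive/mixed/ineligible — that a
    correct curation of the emitted records must reproduce. The truth is
    computed here by direct fraction arithmetic over the records as they
    are constructed, independently of :mod:`pankinet.pkfi`.
    """
    if families is None:
        families = gen_families(config)
    if compounds is None:
        compounds = gen_compounds(config, families)
    fam_by_id = {f.family_id: f for f in families}
    rng, = _streams(config.seed + 1, 1)

    records = []
    truth = {f.family_id: {} for f in families}
    for compound in compounds:
        family = fam_by_id[compound.family_id]
        members = sorted(family.member_kinase_ids)
        cov_hi = config.coverage_max or family.size
        k = int(rng.integers(config.coverage_min, cov_hi + 1))
        tested = [members[i] for i in rng.choice(len(members), size=k,
                                                 replace=False)]
        kept_calls = []
        for kinase_id in tested:
            intended = ACTIVE if compound.pan_active else INACTIVE
            call = intended
            if rng.random() < config.label_noise:
                call = INACTIVE if call == ACTIVE else ACTIVE
            group_calls = [call]
            if rng.random() < config.duplicate_rate:
                n_extra = int(rng.integers(1, 4))
                group_calls += [call] * n_extra
                if rng.random() < config.inconsistency_rate:
                    flip = _inconsistent_split(len(group_calls))
                    other = INACTIVE if call == ACTIVE else ACTIVE
                    group_calls[:flip] = [other] * flip
            for gc in group_calls:
                records.append(_make_record(rng, compound, kinase_id, gc))
            if rng.random() < config.censored_rate:
                rec = _make_record(rng, compound, kinase_id, call)
                records.append(RawActivityRecord(
                    **{**rec.__dict__,
                       "relation": str(rng.choice(["~", ">>"]))}))
            # generator-side consensus: brute-force majority fraction
            counts = {c: group_calls.count(c) for c in set(group_calls)}
            top_call, top_n = max(counts.items(), key=lambda kv: kv[1])
            if top_n / len(group_calls) >= 0.8:
                kept_calls.append(top_call)
        threshold = max(math.ceil(family.size / 2), 2)
        if len(kept_calls) < threshold:
            truth[family.family_id][compound.compound_id] = INELIGIBLE
        elif all(c == ACTIVE for c in kept_calls):
            truth[family.family_id][compound.compound_id] = ACTIVE
        elif all(c == INACTIVE for c in kept_calls):
            truth[family.family_id][compound.compound_id] = INACTIVE
        else:
            truth[family.family_id][compound.compound_id] = MIXED

    perm = np.random.default_rng(config.seed + 2).permutation(len(records))
    records = [records[i] for i in perm]
    logger.info("generated %d activity records for %d compounds",
                len(records), len(compounds))
    return records, truth


def gen_classification_benchmark(config: SyntheticConfig | None = None) -> Benchmark:
    """Balanced planted-motif benchmark for training and attribution tests.

    With the default configuration this yields 400 positives (every one
    carrying the nitrile motif) and 400 negatives from the same scaffold
    library, as a ready-made :class:`~pankinet.pkfi.PKFISet` with
    structures and per-compound motif atom indices.
    """
    if config is None:
        config = SyntheticConfig()
    one_family = SyntheticConfig(**{**config.__dict__, "n_families": 1})
    families = gen_families(one_family)
    compounds = gen_compounds(one_family, families)
    positives = {c.compound_id for c in compounds if c.pan_active}
    negatives = {c.compound_id for c in compounds if not c.pan_active}
    pkfi_set = PKFISet(family_id=families[0].family_id,
                       positives=positives, negatives=negatives)
    return Benchmark(
        pkfi_set=pkfi_set,
        structures={c.compound_id: c.smiles for c in compounds},
        motif_atoms={c.compound_id: c.motif_atoms for c in compounds},
        motif_smarts=one_family.motifs[0],
        compounds=compounds)
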