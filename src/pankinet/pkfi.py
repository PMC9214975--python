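"""Curation of pan-kinase-family inhibitor (PKFI) sets.

A PKFI is a compound that is active against an entire kinase family, as
far as the available bioactivity data can tell. Raw compound-kinase
measurements (IC50 in nM or pKi) are harmonized in four steps:

1. **Filtering** — records with censored/approximate relations (``~``,
   ``>>``) are dropped, as are records failing optional provenance
   attributes (assay type, target type, confidence score) when present.
2. **Binarization** — IC50 < 500 nM or pKi > 6 (both strict) is active.
3. **Duplicate voting** — multiple measurements of the same
   (compound, kinase) pair are merged when at least 80% agree; pairs whose
   maximum consistency is below 80% are excluded outright.
4. **Family labeling** — a compound is *eligible* for family ``F`` when it
   has consensus calls on at least ``max(ceil(|F|/2), 2)`` member kinases;
   an eligible compound is a positive (pan-family active) if every call is
   active, a negative if every call is inactive, and excluded as *mixed*
   otherwise.

The positive class throughout the package is the pan-family ACTIVE class.
Internally the classifier indexes active as class 0 and inactive as
class 1 (:data:`ACTIVE_CLASS_INDEX`, :data:`INACTIVE_CLASS_INDEX`).
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

#: Strict activity cutoff for IC50 measurements, in nM.
IC50_ACTIVE_BELOW_NM = 500.0

#: Strict activity cutoff for pKi measurements.
PKI_ACTIVE_ABOVE = 6.0

#: Minimum agreement fraction for duplicate voting (inclusive).
VOTE_THRESHOLD = 0.80

#: Relations treated as unusable censored/approximate measurements.
EXCLUDED_RELATIONS = frozenset({"~", ">>"})

#: Class index of the pan-family active (positive) class.
ACTIVE_CLASS_INDEX = 0
INACTIVE_CLASS_INDEX = 1

ACTIVE = "active"
INACTIVE = "inactive"
MIXED = "mixed"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class RawActivityRecord:
    """One raw bioactivity measurement of a compound on a kinase."""

    compound_id: str
    smiles: str
    kinase_id: str
    measure: str                 # "IC50_nM" | "pKi"
    relation: str                # '=', '<', '>', '~', '>>'
    value: float
    source: str = "chembl-like"  # "chembl-like" | "profiling-like"
    # Optional provenance attributes; checked by filter_records when present.
    assay_type: str | None = None
    target_type: str | None = None
    confidence: int | None = None

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError(f"activity value must be positive, got {self.value}")


@dataclass(frozen=True)
class BinaryActivity:
    """Consensus active/inactive call for one (compound, kinase) pair."""

    compound_id: str
    kinase_id: str
    label: str  # ACTIVE | INACTIVE


@dataclass(frozen=True)
class KinaseFamily:
    family_id: str
    group: str
    member_kinase_ids: frozenset

    def __post_init__(self):
        if len(self.member_kinase_ids) < 1:
            raise ValueError("a kinase family needs at least one member")

    @property
    def size(self) -> int:
        return len(self.member_kinase_ids)


@dataclass
class PKFISet:
    """Labeled compound set of one kinase family."""

    family_id: str
    positives: set
    negatives: set
    balance_flag: str = ""  # non-empty when balance is undefined

    @property
    def balance(self) -> float:
        """Positive/negative count ratio; NaN when there are no negatives."""
        if not self.negatives:
            return float("nan")
        return len(self.positives) / len(self.negatives)


@dataclass
class DataSplit:
    train: list  # [(compound_id, label), ...]
    test: list
    seed: int


def balance_ratio(n_positives: int, n_negatives: int) -> float:
    """Class balance of a labeled set, positives per negative."""
    if n_negatives == 0:
        return float("nan")
    return n_positives / n_negatives


def filter_records(records):
    """Drop censored-relation records and provenance-failing records.

    Records with relation ``~`` or ``>>`` are removed. When the optional
    ChEMBL-style provenance attributes are present they must read
    "Binding" / "SINGLE PROTEIN" / confidence 9; absent attributes pass.
    Order is preserved.
    """
    kept = []
    for rec in records:
        if rec.relation in EXCLUDED_RELATIONS:
            continue
        if rec.assay_type is not None and rec.assay_type != "Binding":
            continue
        if rec.target_type is not None and rec.target_type != "SINGLE PROTEIN":
            continue
        if rec.confidence is not None and rec.confidence != 9:
            continue
        kept.append(rec)
    logger.info("filter_records: %d/%d records kept", len(kept), len(records))
    return kept


def clean_records(records, structure_key=None):
    """Profiling-style cleaning pass.

    Drops records with missing compound/kinase ids or missing structures,
    and compounds whose canonical structure key collides with a different
    compound id (duplicated-structure removal). ``structure_key`` maps a
    SMILES to a canonical key; by default the canonical SMILES itself.
    """
    from rdkit import Chem

    if structure_key is None:
        def structure_key(smiles):
            mol = Chem.MolFromSmiles(smiles)
            return Chem.MolToSmiles(mol) if mol is not None else None

    key_owner = {}
    dropped_compounds = set()
    keyed = []
    for rec in records:
        if not rec.compound_id or not rec.kinase_id or not rec.smiles:
            continue
        key = structure_key(rec.smiles)
        if key is None:
            continue
        owner = key_owner.setdefault(key, rec.compound_id)
        if owner != rec.compound_id:
            dropped_compounds.update({owner, rec.compound_id})
        keyed.append((rec, key))
    kept = [rec for rec, key in keyed if rec.compound_id not in dropped_compounds]
    logger.info("clean_records: %d/%d records kept", len(kept), len(records))
    return kept


def binarize(record: RawActivityRecord) -> str:
    """Binary activity call from a single measurement (strict cutoffs)."""
    if record.measure == "IC50_nM":
        return ACTIVE if record.value < IC50_ACTIVE_BELOW_NM else INACTIVE
    if record.measure == "pKi":
        return ACTIVE if record.value > PKI_ACTIVE_ABOVE else INACTIVE
    raise ValueError(f"unsupported assay measure: {record.measure!r}")


def vote_duplicates(calls) -> str:
    """80%-consistency vote over duplicate calls for one pair.

    Returns the majority label when its fraction is at least 0.80
    (inclusive), otherwise ``"excluded"``.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("vote_duplicates needs at least one call")
    counts = Counter(calls)
    label, n = counts.most_common(1)[0]
    # Exact-fraction comparison: n/len >= 0.8  <=>  5*n >= 4*len.
    if 5 * n >= 4 * len(calls):
        return label
    return EXCLUDED


def consensus_calls(records) -> list:
    """Binarize and vote all records into per-pair consensus calls.

    Pairs failing the 80% vote are dropped. The output is sorted by
    (compound_id, kinase_id) so it is invariant to record order.
    """
    groups = defaultdict(list)
    for rec in records:
        groups[(rec.compound_id, rec.kinase_id)].append(binarize(rec))
    out = []
    for (cid, kid) in sorted(groups):
        label = vote_duplicates(groups[(cid, kid)])
        if label != EXCLUDED:
            out.append(BinaryActivity(cid, kid, label))
    logger.info("consensus_calls: %d pairs from %d records (%d excluded)",
                len(out), len(records), len(groups) - len(out))
    return out


def eligibility_threshold(family: KinaseFamily) -> int:
    """Minimum number of tested member kinases for PKFI eligibility."""
    return max(math.ceil(family.size / 2), 2)


def is_eligible(compound_tests, family: KinaseFamily) -> bool:
    """True when the compound is tested on enough family members.

    ``compound_tests`` must already be restricted to kinases in the family;
    the compound needs consensus data on at least half the family
    membership (rounded up) and never fewer than two kinases.
    """
    kinases = {t.kinase_id for t in compound_tests}
    if not kinases <= family.member_kinase_ids:
        raise ValueError("compound_tests contain kinases outside the family")
    return len(kinases) >= eligibility_threshold(family)


def label_pkfi(compound_tests) -> str:
    """Pan-family label: unanimous active/inactive, otherwise mixed."""
    labels = {t.label for t in compound_tests}
    if not labels:
        raise ValueError("cannot label a compound with no tests")
    if labels == {ACTIVE}:
        return ACTIVE
    if labels == {INACTIVE}:
        return INACTIVE
    return MIXED


def build_pkfi_set(activities, family: KinaseFamily,
                   structures=None, max_atoms: int = 50) -> PKFISet:
    """Build the labeled PKFI set of one family from consensus calls.

    ``structures`` (compound_id -> SMILES), when given, is used to drop
    compounds exceeding the featurizer's heavy-atom cap so that the set is
    guaranteed to be featurizable downstream.
    """
    from rdkit import Chem

    by_compound = defaultdict(list)
    for act in activities:
        if act.kinase_id in family.member_kinase_ids:
            by_compound[act.compound_id].append(act)

    positives, negatives = set(), set()
    n_mixed = n_ineligible = n_oversize = 0
    for cid in sorted(by_compound):
        tests = by_compound[cid]
        if not is_eligible(tests, family):
            n_ineligible += 1
            continue
        if structures is not None and cid in structures:
            mol = Chem.MolFromSmiles(structures[cid])
            if mol is None or mol.GetNumAtoms() > max_atoms:
                n_oversize += 1
                logger.warning(
                    "dropping %s: unparseable or > %d heavy atoms", cid, max_atoms)
                continue
        label = label_pkfi(tests)
        if label == ACTIVE:
            positives.add(cid)
        elif label == INACTIVE:
            negatives.add(cid)
        else:
            n_mixed += 1

    flag = ""
    if not negatives:
        flag = "no negatives: balance undefined"
        logger.warning("PKFI set %s has no negatives", family.family_id)
    logger.info(
        "build_pkfi_set[%s]: %d positives, %d negatives, %d mixed, "
        "%d ineligible, %d oversize", family.family_id, len(positives),
        len(negatives), n_mixed, n_ineligible, n_oversize)
    return PKFISet(family_id=family.family_id, positives=positives,
                   negatives=negatives, balance_flag=flag)


def split_set(pkfi_set: PKFISet, fraction: float = 0.8,
              seed: int = 0) -> DataSplit:
    """Stratified train/test split of a PKFI set, deterministic per seed."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if len(pkfi_set.positives) < 2 or len(pkfi_set.negatives) < 2:
        raise ValueError("each class needs at least 2 compounds to split")
    items = sorted((cid, ACTIVE) for cid in pkfi_set.positives)
    items += sorted((cid, INACTIVE) for cid in pkfi_set.negatives)
    labels = [lab for _, lab in items]
    train, test = train_test_split(
        items, train_size=fraction, random_state=seed, stratify=labels)
    return DataSplit(train=list(train), test=list(test), seed=seed)
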