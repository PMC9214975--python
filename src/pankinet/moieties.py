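"""Moiety fingerprints and odds-ratio enrichment across a PKFI set.

Grad-CAM highlights *pre-moieties* — conserved local atom environments
that need not coincide with a named functional group. To connect them to
classical descriptors, compounds are fingerprinted against a dictionary of
functional-group SMARTS patterns (in the spirit of the checkmol
vocabulary; a compact default dictionary ships with the package and a
full external dictionary can be loaded from a TSV file), and each
descriptor is scored by its class enrichment on the 2x2 presence table

    a = positives with the moiety     b = positives without
    c = negatives with the moiety     d = negatives without

with a Haldane-style continuity correction applied to all four cells::

    OR = ((a + eps) * (d + eps)) / ((b + eps) * (c + eps)),   eps = 0.5

so the ratio is finite even for empty cells. Descriptors are ranked by
descending odds ratio (ties broken by descriptor id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
from rdkit import Chem

from .featurize import prepare_molecule

logger = logging.getLogger(__name__)

#: Continuity correction added to every cell of the 2x2 table.
EPSILON = 0.5


@dataclass(frozen=True)
class MoietyDescriptor:
    id: int
    name: str
    smarts: str

    @property
    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:  # pragma: no cover - load_dictionary validates patterns
            raise ValueError(f"invalid SMARTS for descriptor {self.id}")
        return q


@dataclass
class EnrichmentRow:
    descriptor_id: int
    name: str
    n_pos_with: int
    n_pos_without: int
    n_neg_with: int
    n_neg_without: int
    odds_ratio: float
    rank: int = 0


def load_dictionary(path=None) -> list:
    """Load a moiety dictionary from a TSV (id, name, smarts).

    Without a path, the package's default functional-group dictionary is
    loaded. Every SMARTS is parsed eagerly so a broken pattern fails at
    load time, not per compound.
    """
    if path is None:
        text = resources.files("pankinet.data").joinpath("moieties.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = [line.split("\t") for line in text.splitlines()[1:] if line.strip()]
    descriptors, seen = [], set()
    for rid, name, smarts in rows:
        did = int(rid)
        if did in seen:
            raise ValueError(f"duplicate descriptor id {did}")
        seen.add(did)
        if Chem.MolFromSmarts(smarts) is None:
            raise ValueError(f"invalid SMARTS {smarts!r} (descriptor {did})")
        descriptors.append(MoietyDescriptor(id=did, name=name, smarts=smarts))
    logger.info("loaded %d moiety descriptors", len(descriptors))
    return descriptors


def fingerprint(smiles_or_mol, dictionary) -> np.ndarray:
    """Binary moiety fingerprint: bit i set iff pattern i matches."""
    mol = (smiles_or_mol if isinstance(smiles_or_mol, Chem.Mol)
           else prepare_molecule(smiles_or_mol))
    return np.array([1 if mol.HasSubstructMatch(d.query) else 0
                     for d in dictionary], dtype=np.uint8)


def odds_ratio(a: int, b: int, c: int, d: int,
               epsilon: float = EPSILON) -> float:
    """Continuity-corrected odds ratio of a 2x2 presence table."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    return ((a + epsilon) * (d + epsilon)) / ((b + epsilon) * (c + epsilon))


def rank_descriptors(pkfi_set, structures: dict, dictionary,
                     epsilon: float = EPSILON, min_support: int = 0) -> list:
    """Odds-ratio ranking of every descriptor over a labeled compound set.

    ``structures`` maps compound ids to SMILES. ``min_support`` drops
    descriptors matched by fewer compounds than the threshold (off by
    default). The result is sorted by descending odds ratio, ties broken
    by ascending descriptor id, with 1-based ranks filled in.
    """
    positives = sorted(pkfi_set.positives)
    negatives = sorted(pkfi_set.negatives)
    if not positives and not negatives:
        raise ValueError("cannot rank descriptors on an empty set")
    missing = [cid for cid in positives + negatives if cid not in structures]
    if missing:
        raise ValueError(f"missing structures for {len(missing)} compounds")

    pos_fp = np.array([fingerprint(structures[cid], dictionary)
                       for cid in positives], dtype=np.uint8)
    neg_fp = np.array([fingerprint(structures[cid], dictionary)
                       for cid in negatives], dtype=np.uint8)
    a = pos_fp.sum(axis=0) if len(positives) else np.zeros(len(dictionary), int)
    c = neg_fp.sum(axis=0) if len(negatives) else np.zeros(len(dictionary), int)

    rows = []
    for i, desc in enumerate(dictionary):
        ai, ci = int(a[i]), int(c[i])
        bi, di = len(positives) - ai, len(negatives) - ci
        if ai + ci < min_support:
            continue
        rows.append(EnrichmentRow(
            descriptor_id=desc.id, name=desc.name,
            n_pos_with=ai, n_pos_without=bi,
            n_neg_with=ci, n_neg_without=di,
            odds_ratio=odds_ratio(ai, bi, ci, di, epsilon)))
    rows.sort(key=lambda r: (-r.odds_ratio, r.descriptor_id))
    for rank, row in enumerate(rows, start=1):
        row.rank = rank
    return rows


def attention_overlap(amap, matched_atom_sets) -> float:
    """Preferential-attention ratio of matched atoms.

    Ratio of the mean attention over the union of matched atom indices to
    the mean attention over all real (non-padded) atoms; 1.0 means no
    preference, > 1 means the attention concentrates on the matches.
    """
    matched = set()
    for s in matched_atom_sets:
        matched |= set(s)
    if not matched:
        raise ValueError("no matched atoms: overlap undefined")
    if not matched <= set(range(amap.n_atoms)):
        raise ValueError("matched atom indices outside the molecule")
    real = amap.scores[:amap.n_atoms]
    overall = float(real.mean())
    if overall == 0:
        return float("nan")
    inside = float(real[sorted(matched)].mean())
    return inside / overall
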