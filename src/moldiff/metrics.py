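"""Generation-quality metrics.

Conventions follow the MOSES benchmark suite: uniqueness/novelty by
canonical-SMILES identity over the *valid* subset, internal diversity from
Morgan fingerprints (radius 2, 2048 bits),

    IntDiv_p = 1 - ( mean over all ordered pairs (i, j), including i = j,
                     of Tanimoto(fp_i, fp_j)^p )^(1/p),

and per-molecule property panels (QED, SAS, logP, TPSA) straight from
RDKit.  The synthetic-accessibility score uses RDKit's bundled
fragment-contribution implementation.
"""

from __future__ import annotations

import json
import os
import sys
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, Descriptors, QED, RDConfig
from rdkit.Chem import rdFingerprintGenerator

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib, present in the rdkit install)

_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

UNDEFINED = float("nan")


@dataclass
class GenerationReport:
    n_requested: int
    n_valid: int
    validity: float
    uniqueness: float
    novelty: float
    intdiv1: float
    intdiv2: float
    property_stats: dict  # name -> {"mean": ..., "sd": ...}
    mad: float | None = None  # conditional runs only
    condition_name: str | None = None
    condition_value: float | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def validity(outputs) -> float:
    """Fraction of decode results that produced a sanitizable molecule
    (``None`` entries are failures)."""
    if not outputs:
        raise ValueError("empty output list")
    return sum(s is not None for s in outputs) / len(outputs)


def uniqueness_novelty(valid, train_set) -> tuple:
    """(|distinct| / |valid|, fraction of distinct SMILES not in train).

    Both inputs must be canonical SMILES; an empty valid list yields
    (nan, nan) rather than zero.
    """
    if not valid:
        return (UNDEFINED, UNDEFINED)
    distinct = set(valid)
    uniq = len(distinct) / len(valid)
    novel = sum(s not in train_set for s in distinct) / len(distinct)
    return uniq, novel


def _fingerprints(smiles):
    return [_FP_GEN.GetFingerprint(Chem.MolFromSmiles(s)) for s in smiles]


def internal_diversity(valid, p: int = 1) -> float:
    """IntDiv_p over all ordered fingerprint pairs, self-pairs included."""
    if len(valid) < 2:
        return UNDEFINED
    fps = _fingerprints(valid)
    sims = np.empty((len(fps), len(fps)))
    for i, fp in enumerate(fps):
        sims[i] = DataStructs.BulkTanimotoSimilarity(fp, fps)
    return float(1.0 - (sims**p).mean() ** (1.0 / p))


def property_panel(valid):
    """Per-molecule QED / SAS / logP / TPSA via RDKit descriptors.

    Returns (records, stats): a list of dicts aligned with the input (a
    molecule whose descriptors fail is excluded with a warning) and the
    aggregate mean/sd per property.
    """
    records = []
    for s in valid:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            warnings.warn(f"descriptor computation skipped unparsable {s!r}")
            continue
        try:
            records.append(
                {
                    "smiles": s,
                    "qed": QED.qed(mol),
                    "sas": sascorer.calculateScore(mol),
                    "logp": Crippen.MolLogP(mol),
                    "tpsa": Descriptors.TPSA(mol),
                }
            )
        except Exception as err:  # pragma: no cover - rdkit descriptor failure
            warnings.warn(f"descriptor failure for {s!r}: {err}")
    stats = {}
    for key in ("qed", "sas", "logp", "tpsa"):
        vals = np.asarray([r[key] for r in records])
        stats[key] = {
            "mean": float(vals.mean()) if len(vals) else UNDEFINED,
            "sd": float(vals.std()) if len(vals) else UNDEFINED,
        }
    return records, stats


def mad(values, target: float) -> float:
    """Mean absolute deviation of generated property values from the
    conditioning target."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value list")
    return float(np.abs(values - target).mean())


def evaluate(
    generated,
    train_smiles,
    condition_name: str | None = None,
    condition_value: float | None = None,
) -> GenerationReport:
    """Full report over raw decode results (``None`` = invalid)."""
    val = validity(generated)
    valid = [s for s in generated if s is not None]
    uniq, novel = uniqueness_novelty(valid, set(train_smiles))
    records, stats = property_panel(valid)
    report_mad = None
    if condition_name is not None and records:
        report_mad = mad([r[condition_name] for r in records], condition_value)
    return GenerationReport(
        n_requested=len(generated),
        n_valid=len(valid),
        validity=val,
        uniqueness=uniq,
        novelty=novel,
        intdiv1=internal_diversity(valid, p=1),
        intdiv2=internal_diversity(valid, p=2),
        property_stats=stats,
        mad=report_mad,
        condition_name=condition_name,
        condition_value=condition_value,
    )
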