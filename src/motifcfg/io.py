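"""File formats, model serialization and evaluation metrics.

FASTA in/out goes through Biopython; models are versioned JSON documents
(``format_version: 1``, unknown fields rejected); scan results and
metrics are TSV.  Every CLI run writes a metadata block (version, seed,
configuration hash) so results can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord
from sklearn.metrics import roc_auc_score

from .alphabet import normalize
from .energy import EnergyParams, default_energy_params
from .profile import ProfileModel

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "save_model",
    "load_model",
    "evaluate",
    "write_scores",
    "metadata_block",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SequenceRecord:
    """An id plus an ACGU RNA sequence (T is normalized to U on input)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", normalize(self.sequence))


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA, preserving order; duplicate ids are an error."""
    out: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(SequenceRecord(rec.id, str(rec.seq)))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(path, records) -> None:
    """Write records wrapped at 60 columns."""
    bio = []
    for r in records:
        rid, seq = (r.id, r.sequence) if isinstance(r, SequenceRecord) else r
        bio.append(_BioRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


# ---------------------------------------------------------------- models

def save_model(path, model: ProfileModel, metadata: dict | None = None) -> None:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "pattern": model.pattern.text,
        "theta_loop": model.theta_loop.tolist(),
        "theta_pair": model.theta_pair.tolist(),
        "theta_bg": model.theta_bg.tolist(),
        "omega": model.omega,
        "lam": model.lam,
        "energy_params": "default",
        "metadata": metadata or {},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


_MODEL_FIELDS = {
    "format_version", "pattern", "theta_loop", "theta_pair", "theta_bg",
    "omega", "lam", "energy_params", "metadata",
}


def load_model(path) -> tuple[ProfileModel, dict]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format_version {doc.get('format_version')!r}"
        )
    unknown = set(doc) - _MODEL_FIELDS
    if unknown:
        raise ValueError(f"unknown model fields: {sorted(unknown)}")
    model = ProfileModel(
        pattern=doc["pattern"],
        theta_loop=np.array(doc["theta_loop"], dtype=float),
        theta_pair=np.array(doc["theta_pair"], dtype=float),
        theta_bg=np.array(doc["theta_bg"], dtype=float),
        omega=float(doc["omega"]),
        lam=float(doc["lam"]),
    )
    return model, doc.get("metadata", {})


# ------------------------------------------------------------- evaluation

def _mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def evaluate(
    pos_scores,
    neg_scores,
    position_posteriors=None,
    truth=None,
    pair_posteriors=None,
    pair_threshold: float = 0.5,
) -> dict:
    """Metric report for a benchmark run.

    ``pos_scores``/``neg_scores``: P(y=1|x) per sequence -> sequence-level
    AUROC.  Optionally, per-positive ``position_posteriors`` (vectors)
    and ``truth`` (objects with ``labels`` strings over S/L/G/B and
    ``pairs``) give position-level AUROCs (overall motif, loop-only,
    stem-only; insertion-gap positions are excluded from the position
    labels) and, with ``pair_posteriors`` (matrices), the Matthews
    correlation between predicted pairs (posterior above threshold
    within the true motif span) and the planted pairs.
    """
    report: dict[str, float] = {}
    y = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    s = np.concatenate([np.asarray(pos_scores), np.asarray(neg_scores)])
    report["sequence_auroc"] = float(roc_auc_score(y, s)) if len(set(y)) == 2 else np.nan

    if position_posteriors is not None and truth is not None:
        ylab: list[int] = []
        yscore: list[float] = []
        lab_loop: list[int] = []
        sc_loop: list[float] = []
        lab_stem: list[int] = []
        sc_stem: list[float] = []
        for post, t in zip(position_posteriors, truth):
            if len(post) != len(t.labels):
                raise ValueError(f"posterior/truth length mismatch for {t.seq_id}")
            for p, (v, lab) in enumerate(zip(post, t.labels)):
                if lab == "G":
                    continue
                is_motif = 1 if lab in "SL" else 0
                ylab.append(is_motif)
                yscore.append(v)
                if lab in "LB":
                    lab_loop.append(is_motif)
                    sc_loop.append(v)
                if lab in "SB":
                    lab_stem.append(is_motif)
                    sc_stem.append(v)
        report["position_auroc"] = float(roc_auc_score(ylab, yscore))
        report["position_auroc_loop"] = float(roc_auc_score(lab_loop, sc_loop))
        report["position_auroc_stem"] = float(roc_auc_score(lab_stem, sc_stem))

    if pair_posteriors is not None and truth is not None:
        tp = tn = fp = fn = 0
        for pp, t in zip(pair_posteriors, truth):
            planted = set(map(tuple, t.pairs))
            lo, hi = t.start, t.end
            for i in range(lo, hi):
                for jj in range(i + 1, hi):
                    pred = pp[i, jj] > pair_threshold
                    true = (i, jj) in planted
                    if pred and true:
                        tp += 1
                    elif pred and not true:
                        fp += 1
                    elif not pred and true:
                        fn += 1
                    else:
                        tn += 1
        report["structure_mcc"] = _mcc(tp, tn, fp, fn)
    return report


def write_scores(path, ids, scores, spans=None, posteriors=None) -> None:
    """Scan output TSV: sequence_id, P(y=1), best motif start/end and,
    optionally, the per-position posterior in wide format."""
    with open(path, "w") as fh:
        cols = ["sequence_id", "prob"]
        if spans is not None:
            cols += ["motif_start", "motif_end"]
        if posteriors is not None:
            cols += ["position_posterior"]
        fh.write("\t".join(cols) + "\n")
        for k, (rid, sc) in enumerate(zip(ids, scores)):
            row = [rid, f"{sc:.6g}"]
            if spans is not None:
                row += [str(spans[k][0]), str(spans[k][1])]
            if posteriors is not None:
                row += [",".join(f"{v:.4g}" for v in posteriors[k])]
            fh.write("\t".join(row) + "\n")


def best_span(posterior: np.ndarray, frac: float = 0.5) -> tuple[int, int]:
    """Contiguous segment around the posterior argmax with values at
    least ``frac`` of the maximum (the reported motif location)."""
    if len(posterior) == 0 or float(np.max(posterior)) <= 0:
        return (0, 0)
    k = int(np.argmax(posterior))
    thr = frac * posterior[k]
    lo = k
    while lo > 0 and posterior[lo - 1] >= thr:
        lo -= 1
    hi = k + 1
    while hi < len(posterior) and posterior[hi] >= thr:
        hi += 1
    return (lo, hi)


def metadata_block(seed: int | None, config: dict) -> dict:
    """Reproducibility metadata attached to every CLI artifact."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "config": config,
    }
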