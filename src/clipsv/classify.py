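"""SV-type classification from 14 depth-normalized pileup attributes.

Classification is post hoc: breakpoints, genotypes and the association
statistic never depend on the predicted type.  Each attribute is the
fraction of reads at the pileup position carrying one mapping signal; the
vector is emitted verbatim in the AT INFO field, and a random forest trained
on labelled vectors assigns the type (WC) and per-class probabilities (WP).

The attribute names and their order are fixed in :data:`ATTRIBUTE_NAMES`;
training files and models are only interchangeable between runs that agree
on this vector.  Some attributes carry little signal on clean data but are
kept so user-supplied training sets can exploit them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .bamio import AlignedRead
from .genotype import InsertStats, MIN_INTERNAL_INDEL

log = logging.getLogger(__name__)

ATTRIBUTE_NAMES = (
    "f_clip_left",              # reads soft/hard-clipped on their left end
    "f_clip_right",             # ... on their right end
    "f_split",                  # reads carrying an SA tag
    "f_alt_aln",                # reads carrying an XA tag
    "f_discordant_insert_long",     # |TLEN| > mu + 3 sigma
    "f_discordant_insert_short",    # 0 < |TLEN| < mu - 3 sigma
    "f_same_strand",            # mate on the same strand (inversion signature)
    "f_everted_pair",           # reversed mate orientation (tandem-dup signature)
    "f_mate_unmapped",
    "f_mate_other_chrom",
    "f_internal_indel",         # CIGAR I/D >= 10 bp
    "f_supplementary",
    "f_low_mapq",               # MAPQ < 20
    "f_duplicate_flagged",
)

N_ATTRIBUTES = len(ATTRIBUTE_NAMES)
LOW_MAPQ = 20

#: forest size; deterministic under a fixed seed.
N_TREES = 200
DEFAULT_K_FOLDS = 5


def _is_everted(read: AlignedRead) -> bool:
    """FR geometry violated with mates on opposite strands (RF orientation)."""
    if not read.is_paired or read.mate_is_unmapped:
        return False
    if read.mate_chrom != read.chrom or read.is_reverse == read.mate_is_reverse:
        return False
    if read.is_reverse:
        return read.pos < read.mate_pos       # reverse read should be rightmost
    return read.pos > read.mate_pos


def _has_internal_indel(read: AlignedRead) -> bool:
    return any(op in "ID" and n >= MIN_INTERNAL_INDEL for op, n in read.cigar)


def extract_attributes(reads: Sequence[AlignedRead],
                       insert_stats: InsertStats) -> List[float]:
    """The 14-attribute vector of one pileup position.

    ``reads`` is the combined (all-samples) pileup.  Each entry is a count
    of reads with the property divided by the pileup depth; an empty pileup
    yields the all-zero vector.
    """
    depth = len(reads)
    if depth == 0:
        return [0.0] * N_ATTRIBUTES
    counts = np.zeros(N_ATTRIBUTES)
    lo = insert_stats.mu - 3.0 * insert_stats.sigma
    hi = insert_stats.upper
    for r in reads:
        cig = r.cigar
        if cig and cig[0][0] in "SH":
            counts[0] += 1
        if cig and len(cig) > 1 and cig[-1][0] in "SH":
            counts[1] += 1
        if r.sa_raw:
            counts[2] += 1
        if r.xa_raw:
            counts[3] += 1
        if r.is_paired and not r.mate_is_unmapped and r.mate_chrom == r.chrom:
            t = abs(r.tlen)
            if t > hi:
                counts[4] += 1
            elif 0 < t < lo:
                counts[5] += 1
        if (r.is_paired and not r.mate_is_unmapped
                and r.mate_chrom == r.chrom and r.is_reverse == r.mate_is_reverse):
            counts[6] += 1
        if _is_everted(r):
            counts[7] += 1
        if r.is_paired and r.mate_is_unmapped:
            counts[8] += 1
        if (r.is_paired and not r.mate_is_unmapped
                and r.mate_chrom not in (None, r.chrom)):
            counts[9] += 1
        if _has_internal_indel(r):
            counts[10] += 1
        if r.is_supplementary:
            counts[11] += 1
        if r.mapq < LOW_MAPQ:
            counts[12] += 1
        if r.is_duplicate:
            counts[13] += 1
    return [float(c) / depth for c in counts]


@dataclass
class TrainingRow:
    attributes: List[float]
    label: str


@dataclass
class ClassifierModel:
    forest: RandomForestClassifier
    classes: List[str]
    seed: int
    cv_score: Optional[float] = None

    def predict(self, at: Sequence[float]) -> Tuple[str, List[float]]:
        """(WC, WP) for one attribute vector; WP follows ``self.classes``."""
        vec = np.asarray(at, dtype=float).reshape(1, -1)
        if vec.shape[1] != N_ATTRIBUTES:
            raise ValueError(f"attribute vector must have {N_ATTRIBUTES} entries")
        if np.any(vec < 0) or np.any(vec > 1):
            raise ValueError("attribute fractions must lie in [0, 1]")
        probs = self.forest.predict_proba(vec)[0]
        order = np.argsort(-probs, kind="stable")
        wc = self.classes[int(order[0])]
        return wc, [float(p) for p in probs]


def train_classifier(rows: Sequence[TrainingRow], seed: int,
                     k: int = DEFAULT_K_FOLDS) -> ClassifierModel:
    """Fit the random forest with stratified k-fold cross-validation.

    The mean CV accuracy is recorded on the model; the returned forest is
    refit on all rows.  A class with fewer than ``k`` rows is an error.
    """
    if not rows:
        raise ValueError("no training rows")
    labels = [r.label for r in rows]
    for cls in sorted(set(labels)):
        n = labels.count(cls)
        if n < k:
            raise ValueError(f"class {cls} has only {n} rows; k={k} needs >= {k}")
    x = np.asarray([r.attributes for r in rows], dtype=float)
    y = np.asarray(labels)
    forest = RandomForestClassifier(n_estimators=N_TREES, random_state=seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    cv = cross_val_score(forest, x, y, cv=skf, scoring="accuracy")
    forest.fit(x, y)
    model = ClassifierModel(forest, [str(c) for c in forest.classes_],
                            seed, float(cv.mean()))
    log.info("classifier: %d rows, %d classes, %d-fold CV accuracy %.4f",
             len(rows), len(model.classes), k, model.cv_score)
    for name, imp in zip(ATTRIBUTE_NAMES, forest.feature_importances_):
        log.debug("feature importance %s = %.4f", name, imp)
    return model


def read_training_file(path: str) -> List[TrainingRow]:
    """Read a tab-delimited training file: 14 attribute columns + label.

    Labels outside DEL/DUP/INS/INV are accepted -- users may train with as
    many variant types as they see fit.
    """
    rows: List[TrainingRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != N_ATTRIBUTES + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {N_ATTRIBUTES + 1} columns, "
                    f"got {len(fields)}")
            try:
                attrs = [float(v) for v in fields[:-1]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            rows.append(TrainingRow(attrs, fields[-1]))
    return rows


def write_training_file(rows: Sequence[TrainingRow], path: str) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(repr(float(v)) for v in r.attributes)
                     + f"\t{r.label}\n")
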