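"""Reading IEDB-style measurement tables, binary labeling, allele filtering, CV splits.

A measurement table is delimited text (comma or tab) whose header names at
least ``allele`` and ``peptide``; the full dialect carries the columns
allele, peptide, measurement_value, measurement_inequality,
measurement_type, measurement_source, original_allele.  Rows that fail
peptide validation or whose measurement cannot be resolved to a binary
label are quarantined with a reason, never dropped silently.

Labeling follows the field's 500 nM convention for quantitative binding
affinity (configurable): affinity <= threshold is a binder.  Inequalities
are honoured: ``<v`` resolves to positive only when v <= threshold, ``>v``
to negative only when v >= threshold; anything else is indeterminate and
quarantined.  Qualitative records map Positive* terms to 1 and Negative to
0; eluted-ligand detections are positives.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .alphabet import InvalidResidueError
from .peptides import (
    NormalizedPeptide,
    PeptideLengthError,
    normalize_to_15mer,
    validate_peptide,
)

DEFAULT_THRESHOLD_NM = 500.0
DEFAULT_MIN_ALLELE_COUNT = 20

_REQUIRED_COLUMNS = ("allele", "peptide")
_POSITIVE_TERMS = {"positive", "positive-high", "positive-intermediate", "positive-low"}
_NEGATIVE_TERMS = {"negative"}

#: preference order when deduplicating (allele, peptide) collisions
_PROVENANCE_RANK = {"BA": 0, "qualitative": 1, "EL": 2}


class SchemaError(ValueError):
    """The table is missing mandatory columns."""


class SplitError(ValueError):
    """A cross-validation split cannot be constructed."""


@dataclass(frozen=True)
class BindingRecord:
    """One allele-peptide measurement row."""

    allele: str
    peptide: str
    measurement_value: float | None = None
    measurement_inequality: str = "="
    measurement_type: str = "quantitative"
    source: str = ""
    original_allele: str = ""
    qualitative_measure: str = ""


@dataclass(frozen=True)
class LabeledExample:
    allele: str
    peptide: NormalizedPeptide
    label: int
    provenance: str  # "BA" or "EL" (qualitative BA collapses to "BA")


@dataclass
class Quarantined:
    row: int
    allele: str
    peptide: str
    reason: str


@dataclass
class DatasetSummary:
    total: int
    retained: int
    positives: int
    allele_counts: dict[str, int] = field(default_factory=dict)
    allele_length_counts: dict[str, dict[int, int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "total": self.total,
            "retained": self.retained,
            "positives": self.positives,
            "allele_counts": self.allele_counts,
            "allele_length_counts": {
                a: {str(k): v for k, v in lc.items()}
                for a, lc in self.allele_length_counts.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def normalize_allele(name: str) -> str:
    return " ".join(str(name).split()).upper().replace("HLA- ", "HLA-")


def _classify_measurement_type(raw: str) -> str:
    t = str(raw).strip().lower()
    if "qual" in t:
        return "qualitative"
    if "elut" in t or "ligand" in t or t in {"el", "ms", "mass spectrometry"}:
        return "EL"
    return "quantitative"


def read_measurement_table(path: str | Path, dialect: str | None = None) -> list[BindingRecord]:
    """Parse a delimited measurement table into :class:`BindingRecord` rows.

    ``dialect`` may be "csv" or "tsv"; by default the separator is sniffed.
    Missing optional columns default sensibly; missing mandatory columns
    raise :class:`SchemaError`.
    """
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower().replace(" ", "_") for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement table missing mandatory column(s): {missing}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        value_raw = d.get("measurement_value", "")
        qual = str(d.get("qualitative_measure", "")).strip()
        try:
            value = float(value_raw) if value_raw not in ("", None) else None
        except ValueError:
            # qualitative dialects carry the call in the value column as text
            value, qual = None, qual or str(value_raw).strip()
        records.append(
            BindingRecord(
                allele=normalize_allele(d["allele"]),
                peptide=str(d["peptide"]).strip(),
                measurement_value=value,
                measurement_inequality=str(d.get("measurement_inequality", "=")).strip() or "=",
                measurement_type=str(d.get("measurement_type", "quantitative")).strip(),
                source=str(d.get("measurement_source", "")),
                original_allele=str(d.get("original_allele", "")),
                qualitative_measure=qual,
            )
        )
    return records


def label_record(
    record: BindingRecord, threshold_nm: float = DEFAULT_THRESHOLD_NM
) -> LabeledExample | str:
    """Resolve one record to a :class:`LabeledExample`, or return a quarantine reason.

    Quantitative affinity: label 1 iff value <= threshold, with
    inequality-aware resolution; indeterminate bounds are quarantined.
    Qualitative: Positive*/Negative terms.  Eluted ligand: positive.
    """
    if threshold_nm <= 0:
        raise ValueError(f"threshold must be positive, got {threshold_nm}")
    try:
        normalized = normalize_to_15mer(validate_peptide(record.peptide))
    except (InvalidResidueError, PeptideLengthError) as exc:
        return f"peptide validation: {exc}"

    kind = _classify_measurement_type(record.measurement_type)
    if kind == "EL":
        return LabeledExample(record.allele, normalized, 1, "EL")
    if kind == "qualitative":
        term = str(record.qualitative_measure or "").strip().lower()
        if term in _POSITIVE_TERMS:
            return LabeledExample(record.allele, normalized, 1, "BA")
        if term in _NEGATIVE_TERMS:
            return LabeledExample(record.allele, normalized, 0, "BA")
        return f"unmappable qualitative term {term!r}"

    value = record.measurement_value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "quantitative record without a numeric measurement value"
    ineq = record.measurement_inequality or "="
    if ineq == "=":
        label = int(value <= threshold_nm)
    elif ineq == "<":
        if value <= threshold_nm:
            label = 1
        else:
            return f"indeterminate bound: <{value:g} does not resolve against {threshold_nm:g} nM"
    elif ineq == ">":
        if value >= threshold_nm:
            label = 0
        else:
            return f"indeterminate bound: >{value:g} does not resolve against {threshold_nm:g} nM"
    else:
        return f"unknown inequality {ineq!r}"
    return LabeledExample(record.allele, normalized, label, "BA")


def label_records(
    records: Sequence[BindingRecord],
    threshold_nm: float = DEFAULT_THRESHOLD_NM,
    deduplicate: bool = True,
) -> tuple[list[LabeledExample], list[Quarantined]]:
    """Label every record; quarantine failures; optionally deduplicate.

    Duplicate (allele, peptide) pairs keep one example, preferring
    quantitative affinity over qualitative over eluted-ligand provenance;
    collisions are resolved deterministically by input order within ties.
    """
    labeled: list[LabeledExample] = []
    quarantine: list[Quarantined] = []
    kinds: list[str] = []
    for i, rec in enumerate(records):
        out = label_record(rec, threshold_nm)
        if isinstance(out, str):
            quarantine.append(Quarantined(i, rec.allele, rec.peptide, out))
        else:
            labeled.append(out)
            k = _classify_measurement_type(rec.measurement_type)
            kinds.append({"quantitative": "BA", "qualitative": "qualitative", "EL": "EL"}[k])
    if deduplicate:
        best: dict[tuple[str, str], tuple[int, int]] = {}
        for idx, (ex, kind) in enumerate(zip(labeled, kinds)):
            key = (ex.allele, ex.peptide.sequence15)
            rank = _PROVENANCE_RANK[kind]
            if key not in best or rank < best[key][0]:
                best[key] = (rank, idx)
        keep = sorted(idx for _, idx in best.values())
        labeled = [labeled[i] for i in keep]
    return labeled, quarantine


def filter_alleles(
    examples: Sequence[LabeledExample],
    min_count: int = DEFAULT_MIN_ALLELE_COUNT,
    total_input: int | None = None,
) -> tuple[list[LabeledExample], DatasetSummary]:
    """Keep only alleles with strictly more than ``min_count`` examples.

    Returns the retained examples and a :class:`DatasetSummary` with
    per-allele counts and length-frequency maps.
    """
    counts: dict[str, int] = {}
    for ex in examples:
        counts[ex.allele] = counts.get(ex.allele, 0) + 1
    kept_alleles = {a for a, c in counts.items() if c > min_count}
    retained = [ex for ex in examples if ex.allele in kept_alleles]
    length_counts: dict[str, dict[int, int]] = {}
    allele_counts: dict[str, int] = {}
    positives = 0
    for ex in retained:
        allele_counts[ex.allele] = allele_counts.get(ex.allele, 0) + 1
        lc = length_counts.setdefault(ex.allele, {})
        L = ex.peptide.original_length
        lc[L] = lc.get(L, 0) + 1
        positives += ex.label
    summary = DatasetSummary(
        total=len(examples) if total_input is None else total_input,
        retained=len(retained),
        positives=positives,
        allele_counts=allele_counts,
        allele_length_counts=length_counts,
    )
    return retained, summary


def shuffle_and_split(
    n_examples: int, k: int = 5, seed: int = 0, labels: Sequence[int] | None = None
) -> list[np.ndarray]:
    """Seeded global shuffle followed by k near-equal folds of example indices.

    Returns the k held-out index arrays (a partition of ``range(n_examples)``);
    remainder examples go to the lowest-index folds.  Pass ``labels`` to get
    stratified folds instead of the default plain shuffle.
    """
    if k < 2:
        raise SplitError(f"need at least 2 folds, got k={k}")
    if n_examples < k:
        raise SplitError(f"cannot split {n_examples} examples into {k} folds")
    if labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros(n_examples), np.asarray(labels))]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n_examples))]


def write_labeled_table(examples: Iterable[LabeledExample], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("allele\tsequence15\toriginal_length\tlabel\tprovenance\n")
        for ex in examples:
            fh.write(
                f"{ex.allele}\t{ex.peptide.sequence15}\t{ex.peptide.original_length}"
                f"\t{ex.label}\t{ex.provenance}\n"
            )


def write_quarantine_report(quarantine: Iterable[Quarantined], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("row\tallele\tpeptide\treason\n")
        for q in quarantine:
            fh.write(f"{q.row}\t{q.allele}\t{q.peptide}\t{q.reason}\n")
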