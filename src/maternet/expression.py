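"""Expression tables, detection calls, and two-condition differential contrasts.

Tables hold per-gene signal / detection-p pairs for one stage and condition
(the shape of a BeadStudio-style export). Detection follows an inclusive
``detection p <= threshold`` rule; fold change is the max/min ratio of floored
linear-scale mean signals, with direction expressed relative to the control
condition (``up`` means higher in the non-control table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, ValidationError

STAGES = ("stage1", "stage2")
CONDITIONS = ("ctrl", "NSN")

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_UNCHANGED = "unchanged"
DIRECTION_NOT_EXPRESSED = "not_expressed"


def normalize_gene(symbol: str) -> str:
    """Uppercase a gene symbol; reject empty or whitespace-containing symbols."""
    sym = str(symbol).strip()
    if not sym:
        raise ValidationError("empty gene symbol")
    if any(c.isspace() for c in sym):
        raise ValidationError(f"gene symbol contains whitespace: {sym!r}")
    return sym.upper()


@dataclass(frozen=True)
class ContrastThresholds:
    """Thresholds of one differential contrast.

    fc_threshold is inclusive (a ratio exactly at the threshold is regulated);
    detp_threshold is inclusive (a detection p exactly at the threshold is
    expressed); signal_floor guards the ratio against non-positive signals
    left over from background subtraction.
    """

    fc_threshold: float = 1.5
    detp_threshold: float = 0.01
    signal_floor: float = 1.0

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValidationError("fc_threshold must be > 1")
        if not 0 < self.detp_threshold < 1:
            raise ValidationError("detp_threshold must be in (0, 1)")
        if not self.signal_floor > 0:
            raise ValidationError("signal_floor must be positive")


@dataclass
class ExpressionTable:
    """Per-gene signal and detection p across the samples of one stage/condition."""

    stage: str
    condition: str
    signal: pd.DataFrame  # genes x samples, non-negative finite
    detp: pd.DataFrame  # genes x samples, in [0, 1]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if not self.sample_ids:
            self.sample_ids = list(self.signal.columns)
        if len(self.sample_ids) == 0:
            raise ValidationError("table needs at least one sample")
        if self.signal.index.has_duplicates:
            dups = self.signal.index[self.signal.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene symbols: {dups}")
        if not ((self.detp.values >= 0) & (self.detp.values <= 1)).all():
            raise ValidationError("detection p values must lie in [0, 1]")
        import numpy as np

        if not np.isfinite(self.signal.values).all():
            raise ValidationError("signals must be finite")

    @property
    def genes(self) -> list[str]:
        return list(self.signal.index)

    def mean_signal(self) -> pd.Series:
        return self.signal.mean(axis=1)

    def min_detp(self) -> pd.Series:
        """Per-gene detection-p summary: minimum across samples (permissive)."""
        return self.detp.min(axis=1)


@dataclass(frozen=True)
class ContrastCall:
    """Differential status of one gene for a two-condition contrast."""

    gene: str
    fold_change: float
    direction: str
    expressed_in: frozenset[str]  # subset of {"ctrl", "NSN"}

    def __post_init__(self) -> None:
        if (self.direction == DIRECTION_NOT_EXPRESSED) != (len(self.expressed_in) == 0):
            raise ValidationError(
                f"{self.gene}: direction/expressed_in inconsistent "
                f"({self.direction}, {set(self.expressed_in)})"
            )
        if self.fold_change < 1:
            raise ValidationError(f"{self.gene}: fold_change {self.fold_change} < 1")


def load_expression_table(path, stage: str, condition: str) -> ExpressionTable:
    """Read the expression TSV dialect.

    Header: ``gene<TAB>{sample}.signal<TAB>{sample}.detp ...``; ``#`` lines are
    comments. Symbols are uppercased; duplicates (post-normalization) are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.shape[1] < 3 or df.columns[0] != "gene":
        raise FormatError(f"{path}: first column must be 'gene'")
    samples: list[str] = []
    for col in df.columns[1:]:
        if col.endswith(".signal"):
            samples.append(col[: -len(".signal")])
        elif not col.endswith(".detp"):
            raise FormatError(f"{path}: unrecognized column {col!r}")
    if not samples:
        raise FormatError(f"{path}: no '.signal' columns found")
    for s in samples:
        if f"{s}.detp" not in df.columns:
            raise FormatError(f"{path}: missing column {s + '.detp'!r}")

    genes = []
    seen = {}
    for i, raw in enumerate(df["gene"]):
        g = normalize_gene(raw)
        if g in seen:
            raise ValidationError(
                f"{path}: duplicate gene symbol {g!r} (rows {seen[g] + 2} and {i + 2})"
            )
        seen[g] = i
        genes.append(g)

    signal = df[[f"{s}.signal" for s in samples]].astype(float)
    signal.columns = samples
    signal.index = genes
    detp = df[[f"{s}.detp" for s in samples]].astype(float)
    detp.columns = samples
    detp.index = genes

    bad = ~((detp.values >= 0) & (detp.values <= 1))
    if bad.any():
        row = int(bad.any(axis=1).argmax())
        raise ValidationError(
            f"{path}: detection p outside [0, 1] at data row {row + 1} (gene {genes[row]})"
        )
    return ExpressionTable(stage=stage, condition=condition, signal=signal, detp=detp,
                           sample_ids=samples)


def write_expression_table(table: ExpressionTable, path) -> None:
    """Write the expression TSV dialect read by :func:`load_expression_table`."""
    cols = []
    for s in table.sample_ids:
        cols.append((f"{s}.signal", table.signal[s]))
        cols.append((f"{s}.detp", table.detp[s]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# stage=%s condition=%s\n" % (table.stage, table.condition))
        fh.write("gene\t" + "\t".join(name for name, _ in cols) + "\n")
        for gene in table.genes:
            values = "\t".join(f"{series[gene]:.6g}" for _, series in cols)
            fh.write(f"{gene}\t{values}\n")


def call_expressed(table: ExpressionTable,
                   thresholds: ContrastThresholds | None = None) -> dict[str, bool]:
    """Flag each gene expressed iff min detection p across samples <= threshold."""
    thresholds = thresholds or ContrastThresholds()
    if len(table.genes) == 0:
        raise ValidationError("empty expression table")
    summary = table.min_detp()
    return {g: bool(p <= thresholds.detp_threshold) for g, p in summary.items()}


def fold_change(mean_ctrl: float, mean_nsn: float, floor: float) -> tuple[float, str]:
    """Floored max/min ratio and NSN-relative direction.

    Both means are floored at ``floor`` before division. Direction is ``up``
    when the floored NSN mean exceeds the floored control mean, ``down`` when
    below, ``unchanged`` when equal; the threshold decision is the caller's.
    """
    if not floor > 0:
        raise ValidationError("floor must be positive")
    if not (math.isfinite(mean_ctrl) and math.isfinite(mean_nsn)):
        raise ValidationError("non-finite mean signal")
    a = max(mean_ctrl, floor)
    b = max(mean_nsn, floor)
    ratio = max(a, b) / min(a, b)
    if b > a:
        direction = DIRECTION_UP
    elif b < a:
        direction = DIRECTION_DOWN
    else:
        direction = DIRECTION_UNCHANGED
    return ratio, direction


def differential_contrast(ctrl: ExpressionTable, nsn: ExpressionTable,
                          thresholds: ContrastThresholds | None = None) -> list[ContrastCall]:
    """Call up/down/unchanged/not_expressed over the gene union of two tables.

    A gene absent from one table counts as undetected there (detection p = 1,
    signal at the floor). A gene expressed in at least one condition with
    ratio >= fc_threshold is directional; expressed below threshold is
    unchanged; expressed nowhere is not_expressed. Output sorted by gene.
    """
    thresholds = thresholds or ContrastThresholds()
    if ctrl.stage != nsn.stage:
        raise ValidationError(f"stage mismatch: {ctrl.stage} vs {nsn.stage}")
    expr_ctrl = call_expressed(ctrl, thresholds)
    expr_nsn = call_expressed(nsn, thresholds)
    mean_ctrl = ctrl.mean_signal()
    mean_nsn = nsn.mean_signal()

    calls: list[ContrastCall] = []
    for gene in sorted(set(ctrl.genes) | set(nsn.genes)):
        e_ctrl = expr_ctrl.get(gene, False)
        e_nsn = expr_nsn.get(gene, False)
        m_ctrl = float(mean_ctrl.get(gene, 0.0))
        m_nsn = float(mean_nsn.get(gene, 0.0))
        ratio, direction = fold_change(m_ctrl, m_nsn, thresholds.signal_floor)
        expressed_in = frozenset(
            c for c, flag in (("ctrl", e_ctrl), ("NSN", e_nsn)) if flag
        )
        if not expressed_in:
            direction = DIRECTION_NOT_EXPRESSED
        elif ratio < thresholds.fc_threshold or direction == DIRECTION_UNCHANGED:
            direction = DIRECTION_UNCHANGED
        calls.append(ContrastCall(gene=gene, fold_change=ratio, direction=direction,
                                  expressed_in=expressed_in))
    return calls


def write_contrast_calls(calls: list[ContrastCall], path) -> None:
    """Write a ContrastCall TSV: gene, direction, fold_change, expressed_in."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tdirection\tfold_change\texpressed_in\n")
        for c in calls:
            expr = ",".join(sorted(c.expressed_in))
            fh.write(f"{c.gene}\t{c.direction}\t{c.fold_change:.6g}\t{expr}\n")


def read_contrast_calls(path) -> list[ContrastCall]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    needed = {"gene", "direction", "fold_change", "expressed_in"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    calls = []
    for _, row in df.iterrows():
        expr = frozenset(x for x in str(row["expressed_in"]).split(",")
                         if x and x != "nan")
        calls.append(ContrastCall(gene=normalize_gene(row["gene"]),
                                  fold_change=float(row["fold_change"]),
                                  direction=row["direction"], expressed_in=expr))
    return calls
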