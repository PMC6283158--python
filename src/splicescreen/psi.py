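"""PSI quantification and empirical differential-splicing test.

Per-sample percent-spliced-in (PSI) of an event is the TPM share of its
inclusion isoforms::

    PSI = sum TPM(inclusion) / (sum TPM(inclusion) + sum TPM(exclusion))

A sample's PSI is undefined (NA) when the denominator falls below the
expression floor (default 1 TPM).  The difference of condition means,
dPSI = mean(mutant) - mean(control), is tested against an empirical,
abundance-matched null assembled from within-condition between-replicate
PSI differences pooled across events (see :func:`delta_psi_test`).
Events are flagged significant for |dPSI| >= 0.1 and p < 0.01.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .events import SpliceEvent

CONTROL, MUTANT = "control", "mutant"


@dataclass
class QuantTable:
    """Per-sample transcript TPMs plus the sample-to-condition design."""

    samples: list[str]
    design: dict[str, tuple[str, int]]  # sample -> (condition, replicate)
    tpm: pd.DataFrame  # index: transcript_id, columns: samples

    def __post_init__(self) -> None:
        missing = [s for s in self.samples if s not in self.tpm.columns]
        if missing:
            raise ValueError(f"samples missing from TPM table: {missing}")
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("negative TPM values in quantification table")

    def condition_samples(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.design[s][0] == condition]

    def transcript_tpm(self, transcripts, sample: str) -> float:
        if sample not in self.design:
            raise KeyError(f"unknown sample id {sample!r}")
        total = 0.0
        for tid in transcripts:
            if tid in self.tpm.index:
                total += float(self.tpm.at[tid, sample])
            else:
                warnings.warn(f"transcript {tid} absent from quantification; treated as 0 TPM")
        return total


def read_quantifications(quant_dir: str | Path, design_path: str | Path) -> QuantTable:
    """Load Salmon-style per-sample TSVs (columns Name, TPM) plus a design TSV.

    The design file has columns ``sample``, ``condition``, ``replicate`` and
    optionally ``path``; without a path column, ``<quant_dir>/<sample>.tsv``
    is read for each sample.
    """
    design = pd.read_csv(design_path, sep="\t", comment="#")
    required = {"sample", "condition", "replicate"}
    if not required <= set(design.columns):
        raise ValueError(f"design file must have columns {sorted(required)}")
    quant_dir = Path(quant_dir)
    cols = {}
    for _, row in design.iterrows():
        path = Path(row["path"]) if "path" in design.columns else quant_dir / f"{row['sample']}.tsv"
        tab = pd.read_csv(path, sep="\t")
        if "Name" not in tab.columns or "TPM" not in tab.columns:
            raise ValueError(f"{path}: expected Salmon-style columns Name and TPM")
        cols[row["sample"]] = tab.set_index("Name")["TPM"].astype(float)
    tpm = pd.DataFrame(cols).fillna(0.0)
    return QuantTable(
        samples=list(design["sample"]),
        design={r["sample"]: (r["condition"], int(r["replicate"])) for _, r in design.iterrows()},
        tpm=tpm,
    )


@dataclass
class PsiRecord:
    event_id: str
    psi: dict[str, float]  # sample -> PSI (NaN when undefined)
    mean_psi_by_condition: dict[str, float]
    delta_psi: float
    p_value: float
    q_value: float = math.nan
    significant: bool = False
    direction: str | None = None  # more_included | less_included
    total_tpm: dict[str, float] = field(default_factory=dict)


def compute_psi(event: SpliceEvent, quant: QuantTable, sample: str,
                expression_floor: float = 1.0) -> float:
    """Per-sample PSI of one event; NaN below the expression floor."""
    inc = quant.transcript_tpm(event.inclusion_transcripts, sample)
    exc = quant.transcript_tpm(event.exclusion_transcripts, sample)
    total = inc + exc
    if total < expression_floor:
        return math.nan
    return inc / total


def isoform_fractions(gene_id: str, transcripts, quant: QuantTable,
                      sample: str) -> dict[str, float]:
    """TPM share of each isoform of a gene in one sample (NaN map if silent)."""
    tpms = {}
    for t in transcripts:
        tid = t.transcript_id if hasattr(t, "transcript_id") else t
        tpms[tid] = quant.transcript_tpm([tid], sample)
    total = sum(tpms.values())
    if total <= 0:
        return {tid: math.nan for tid in tpms}
    return {tid: v / total for tid, v in tpms.items()}


def psi_table(events: list[SpliceEvent], quant: QuantTable,
              expression_floor: float = 1.0) -> pd.DataFrame:
    """Per-event rows with ``psi_<sample>`` and ``tpm_<sample>`` columns."""
    # vectorised lookup: restrict the TPM matrix to referenced transcripts
    rows = []
    tpm = quant.tpm
    known = set(tpm.index)
    warned: set[str] = set()
    for ev in events:
        inc = [t for t in ev.inclusion_transcripts if t in known]
        exc = [t for t in ev.exclusion_transcripts if t in known]
        for t in (ev.transcripts - known) - warned:
            warnings.warn(f"transcript {t} absent from quantification; treated as 0 TPM")
            warned.add(t)
        inc_tpm = tpm.loc[inc, quant.samples].sum(axis=0) if inc else pd.Series(0.0, index=quant.samples)
        exc_tpm = tpm.loc[exc, quant.samples].sum(axis=0) if exc else pd.Series(0.0, index=quant.samples)
        total = inc_tpm + exc_tpm
        psi = inc_tpm / total.where(total >= expression_floor)
        row = {"event_id": ev.event_id, "type": ev.type, "gene_id": ev.gene_id,
               "first_intron": ev.first_intron}
        for s in quant.samples:
            row[f"psi_{s}"] = psi[s]
            row[f"tpm_{s}"] = total[s]
        rows.append(row)
    return pd.DataFrame(rows)


def delta_psi_test(
    events: list[SpliceEvent],
    quant: QuantTable,
    expression_bins: int = 10,
    seed: int | None = None,
    dpsi_threshold: float = 0.1,
    alpha: float = 0.01,
    expression_floor: float = 1.0,
) -> list[PsiRecord]:
    """Differential splicing between mutant and control conditions.

    Builds the per-sample PSI table and applies the abundance-matched
    empirical test of :func:`delta_psi_test_from_table`.
    """
    table = psi_table(events, quant, expression_floor)
    return delta_psi_test_from_table(
        table, quant.design, expression_bins=expression_bins, seed=seed,
        dpsi_threshold=dpsi_threshold, alpha=alpha,
    )


def delta_psi_test_from_table(
    table: pd.DataFrame,
    design: dict[str, tuple[str, int]],
    expression_bins: int = 10,
    seed: int | None = None,
    dpsi_threshold: float = 0.1,
    alpha: float = 0.01,
) -> list[PsiRecord]:
    """Empirical differential test on a PSI table.

    The null distribution for |dPSI| is assembled from the absolute
    within-condition between-replicate PSI differences of all testable
    events, scaled by sqrt((1/n_mut + 1/n_ctl)/2) so that a single-pair
    difference matches the sampling variance of a difference of condition
    means.  Null values are pooled within quantile bins of mean total
    event TPM (abundance matching) and the p-value of an event is::

        p = (1 + #{null values in its bin >= |dPSI|}) / (1 + N_bin)

    The procedure involves no resampling, hence is deterministic; ``seed``
    is accepted for interface stability and unused.

    Events with any undefined replicate PSI are excluded from testing and
    reported with ``p = NaN``.  Raises ``ValueError`` with fewer than two
    replicates in either condition.
    """
    ctl = [s for s, (c, _) in design.items() if c == CONTROL]
    mut = [s for s, (c, _) in design.items() if c == MUTANT]
    if len(ctl) < 2 or len(mut) < 2:
        raise ValueError(
            f"need >= 2 replicates per condition, got {len(ctl)} control / {len(mut)} mutant"
        )

    psi_cols = {s: f"psi_{s}" for s in ctl + mut}
    tpm_cols = [f"tpm_{s}" for s in ctl + mut]
    psi_c = table[[psi_cols[s] for s in ctl]].to_numpy(float)
    psi_m = table[[psi_cols[s] for s in mut]].to_numpy(float)
    mean_tpm = table[tpm_cols].to_numpy(float).mean(axis=1)

    testable = ~np.isnan(psi_c).any(axis=1) & ~np.isnan(psi_m).any(axis=1)
    dpsi = np.nanmean(psi_m, axis=1) - np.nanmean(psi_c, axis=1)

    scale = math.sqrt((1.0 / len(mut) + 1.0 / len(ctl)) / 2.0)
    null_chunks = []
    for block in (psi_c, psi_m):
        n = block.shape[1]
        for i in range(n):
            for j in range(i + 1, n):
                null_chunks.append(np.abs(block[:, i] - block[:, j]) * scale)
    nulls = np.vstack(null_chunks)  # (n_pairs, n_events)

    p = np.full(len(table), np.nan)
    idx = np.where(testable)[0]
    if idx.size:
        nbins = max(1, min(expression_bins, idx.size))
        edges = np.quantile(mean_tpm[idx], np.linspace(0, 1, nbins + 1))
        bins = np.clip(np.searchsorted(edges[1:-1], mean_tpm[idx], side="right"), 0, nbins - 1)
        for b in range(nbins):
            members = idx[bins == b]
            pool = np.sort(nulls[:, members].ravel())
            pool = pool[~np.isnan(pool)]
            ge = len(pool) - np.searchsorted(pool, np.abs(dpsi[members]), side="left")
            p[members] = (1.0 + ge) / (1.0 + len(pool))

    q = np.full(len(table), np.nan)
    if idx.size:
        q[idx] = multipletests(p[idx], method="fdr_bh")[1]

    records = []
    for i, row in enumerate(table.itertuples(index=False)):
        tested = bool(testable[i])
        d = float(dpsi[i]) if tested else math.nan
        pv = float(p[i])
        sig = tested and abs(d) >= dpsi_threshold and pv < alpha
        records.append(
            PsiRecord(
                event_id=row.event_id,
                psi={s: float(getattr(row, psi_cols[s])) for s in ctl + mut},
                mean_psi_by_condition={
                    CONTROL: float(np.nanmean(psi_c[i])) if not np.isnan(psi_c[i]).all() else math.nan,
                    MUTANT: float(np.nanmean(psi_m[i])) if not np.isnan(psi_m[i]).all() else math.nan,
                },
                delta_psi=d,
                p_value=pv,
                q_value=float(q[i]),
                significant=sig,
                direction=(None if not tested or d == 0
                           else ("more_included" if d > 0 else "less_included")),
                total_tpm={s: float(getattr(row, f"tpm_{s}")) for s in ctl + mut},
            )
        )
    return records


def records_to_frame(records: list[PsiRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "event_id": r.event_id,
            "mean_psi_control": r.mean_psi_by_condition.get(CONTROL),
            "mean_psi_mutant": r.mean_psi_by_condition.get(MUTANT),
            "delta_psi": r.delta_psi,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "significant": r.significant,
            "direction": r.direction or "",
        }
        for s, v in r.psi.items():
            row[f"psi_{s}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
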