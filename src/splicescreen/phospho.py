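"""iTRAQ phosphoproteomics differential-abundance statistics.

Peptide-spectrum matches (PSMs) carrying phospho modifications are mapped
to canonical phosphosite notations of the form ``amino acid:protein:
position`` so that all spectra of the same site collapse to one key:

* single unambiguous site, one master protein:  ``Phospho:S:ACC:24``
* multiple master proteins: positions are chained per accession in input
  order, ``Phospho:S:ACC1:102:ACC2:103:ACC3:103``
* ambiguous residue class (no explicit position): candidate positions are
  joined by ``/`` and residue classes by ``|``, e.g.
  ``S:ACC:146/149/153/156|T:ACC:148`` (no ``Phospho:`` prefix in this
  dialect).

Per replicate, the normalized reporter-ion abundances of all PSMs of a
site are summed in the control and treatment channels, the log2 ratio
treatment/control is computed, and ratios are standardised into Z-scores
within each replicate's site table.  Every site detected in two or more
replicates is tested for deviation from unchanged abundance by combining
its Z-scores under a standard-normal model (Stouffer: sum z / sqrt(k),
two-sided).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class PhosphoError(ValueError):
    pass


@dataclass(frozen=True)
class PhosphoMod:
    """One phospho annotation: positioned residue or ambiguous residue class."""

    residues: tuple[str, ...]           # e.g. ("S",) or ("T", "S")
    position: int | None = None         # 1-based in peptide; None when ambiguous
    score: float | None = None          # localization score, annotation only

    @property
    def ambiguous(self) -> bool:
        return self.position is None


@dataclass
class PsmRecord:
    peptide: str
    modification: list[PhosphoMod]
    master_proteins: list[str]
    abundance_control: float
    abundance_treatment: float
    replicate: int
    peptide_start: dict[str, int] = field(default_factory=dict)
    preceding: str = ""
    following: str = ""


_MOD_RE = re.compile(r"(?:\d+x)?Phospho\s*\[([^\]]+)\]")
_POS_TOKEN = re.compile(r"^([STY])(\d+)(?:\(([\d.]+)\))?$")


def parse_modification(text: str) -> list[PhosphoMod]:
    """Parse a Proteome-Discoverer-style phospho annotation string.

    Supported dialects: ``Phospho [S3(100)]``, ``Phospho [S3(99.1); T5(80)]``
    and ambiguous residue classes ``Phospho [T/S]`` or ``Phospho [S]``.
    """
    m = _MOD_RE.search(text)
    if not m:
        raise PhosphoError(f"no phospho annotation found in {text!r}")
    mods: list[PhosphoMod] = []
    for token in m.group(1).split(";"):
        token = token.strip()
        pm = _POS_TOKEN.match(token)
        if pm:
            residue, pos, score = pm.group(1), int(pm.group(2)), pm.group(3)
            mods.append(PhosphoMod((residue,), pos, float(score) if score else None))
        else:
            residues = tuple(r.strip() for r in token.split("/"))
            if not all(r in "STY" for r in residues):
                raise PhosphoError(f"unparseable phospho token {token!r}")
            mods.append(PhosphoMod(residues))
    return mods


def notate_site(psm: PsmRecord) -> str:
    """Canonical site notation for one PSM (see module docstring).

    Protein positions are ``peptide_start + position_in_peptide - 1``.
    Multiple positioned modifications on one peptide are chained with ``+``
    in peptide-position order so distinct multi-site species never collide.
    """
    for acc in psm.master_proteins:
        if acc not in psm.peptide_start:
            raise PhosphoError(f"no peptide start for master protein {acc}")
    parts = []
    for mod in sorted(psm.modification, key=lambda m: (m.position or 0, m.residues)):
        if not mod.ambiguous:
            residue, pos = mod.residues[0], mod.position
            if pos is None or pos > len(psm.peptide):
                raise PhosphoError(
                    f"modification position {pos} exceeds peptide length {len(psm.peptide)}"
                )
            if psm.peptide[pos - 1] != residue:
                raise PhosphoError(
                    f"modification {residue}{pos} does not match peptide residue "
                    f"{psm.peptide[pos - 1]!r} in {psm.peptide}"
                )
            chain = ":".join(
                f"{acc}:{psm.peptide_start[acc] + pos - 1}" for acc in psm.master_proteins
            )
            parts.append(f"Phospho:{residue}:{chain}")
        else:
            classes = []
            for residue in sorted(set(mod.residues)):
                pep_positions = [i + 1 for i, aa in enumerate(psm.peptide) if aa == residue]
                if not pep_positions:
                    raise PhosphoError(
                        f"ambiguous residue {residue} absent from peptide {psm.peptide}"
                    )
                chain = ":".join(
                    f"{acc}:" + "/".join(str(psm.peptide_start[acc] + p - 1) for p in pep_positions)
                    for acc in psm.master_proteins
                )
                classes.append(f"{residue}:{chain}")
            parts.append("|".join(classes))
    return "+".join(parts)


def parse_site_notation(notation: str) -> list[dict]:
    """Invert :func:`notate_site` back to residue/protein/position content."""
    sites = []
    for part in notation.split("+"):
        for cls in part.split("|"):
            tokens = cls.split(":")
            if tokens[0] == "Phospho":
                tokens = tokens[1:]
                prefixed = True
            else:
                prefixed = False
            residue = tokens[0]
            rest = tokens[1:]
            if len(rest) % 2:
                raise PhosphoError(f"malformed notation {notation!r}")
            positions = {}
            for acc, pos in zip(rest[::2], rest[1::2]):
                positions[acc] = [int(p) for p in pos.split("/")]
            sites.append({"residue": residue, "positions": positions,
                          "ambiguous": not prefixed})
    return sites


def compute_peptide_starts(peptide: str, accessions: list[str],
                           proteins: dict[str, str]) -> dict[str, int]:
    """Locate a peptide in each master protein sequence (1-based start)."""
    starts = {}
    for acc in accessions:
        if acc not in proteins:
            raise PhosphoError(f"master protein {acc} not in protein FASTA")
        idx = proteins[acc].find(peptide)
        if idx < 0:
            raise PhosphoError(f"peptide {peptide} not found in {acc}")
        starts[acc] = idx + 1
    return starts


@dataclass
class SiteReplicateStat:
    site: str
    replicate: int
    sum_control: float
    sum_treatment: float
    log_ratio: float
    z: float = math.nan


@dataclass
class SiteTestResult:
    site: str
    k: int
    combined_z: float
    p_value: float
    direction: str  # gain | loss
    per_replicate_flags: dict[int, bool]
    mean_log_ratio: float
    q_value: float = math.nan


def aggregate_sites(psms: list[PsmRecord]) -> list[SiteReplicateStat]:
    """Sum abundances per (site, replicate) and Z-standardise log-ratios.

    Standardisation uses the sample standard deviation (ddof=1) over all
    sites within each replicate's table.  Site-replicates with a zero sum
    in either channel carry no usable ratio and are excluded with a
    warning.
    """
    sums: dict[tuple[str, int], list[float]] = {}
    for psm in psms:
        key = (notate_site(psm), psm.replicate)
        acc = sums.setdefault(key, [0.0, 0.0])
        acc[0] += psm.abundance_control
        acc[1] += psm.abundance_treatment

    stats: list[SiteReplicateStat] = []
    for (site, rep), (c, t) in sorted(sums.items()):
        if c <= 0 or t <= 0:
            warnings.warn(f"site {site} replicate {rep}: zero channel sum; excluded")
            continue
        stats.append(SiteReplicateStat(site, rep, c, t, math.log2(t / c)))

    by_rep: dict[int, list[SiteReplicateStat]] = {}
    for s in stats:
        by_rep.setdefault(s.replicate, []).append(s)
    for rep, group in by_rep.items():
        lrs = np.array([s.log_ratio for s in group])
        mu = lrs.mean()
        sd = lrs.std(ddof=1) if len(lrs) > 1 else math.nan
        for s in group:
            s.z = (s.log_ratio - mu) / sd if sd and sd > 0 else math.nan
    return stats


def combine_test(site_stats: list[SiteReplicateStat], z_cutoff: float = 1.96,
                 method: str = "stouffer") -> SiteTestResult:
    """Test one site's Z-scores for deviation from unchanged abundance.

    ``stouffer`` (default): combined z = sum z_i / sqrt(k) referred to the
    standard normal, two-sided.  ``one_sample_t``: one-sample t-test of
    the z-scores against 0 (alternative reading with estimated variance).
    Sites with fewer than two Z-scores are not tested (p = NaN).
    """
    if not site_stats:
        raise PhosphoError("no replicate statistics supplied")
    site = site_stats[0].site
    zs = np.array([s.z for s in site_stats if not math.isnan(s.z)])
    lrs = np.array([s.log_ratio for s in site_stats if not math.isnan(s.z)])
    k = len(zs)
    flags = {s.replicate: (abs(s.z) >= z_cutoff if not math.isnan(s.z) else False)
             for s in site_stats}
    mean_lr = float(lrs.mean()) if k else math.nan
    direction = "gain" if mean_lr > 0 else "loss"
    if k < 2:
        return SiteTestResult(site, k, math.nan, math.nan, direction, flags, mean_lr)
    if method == "stouffer":
        combined = float(zs.sum() / math.sqrt(k))
        p = float(2.0 * sps.norm.sf(abs(combined)))
    elif method == "one_sample_t":
        combined, p = sps.ttest_1samp(zs, 0.0)
        combined, p = float(combined), float(p)
    else:
        raise ValueError(f"unknown combining method {method!r}")
    return SiteTestResult(site, k, combined, p, direction, flags, mean_lr)


def site_tests(psms: list[PsmRecord], z_cutoff: float = 1.96,
               method: str = "stouffer") -> list[SiteTestResult]:
    """Aggregate, test every site, and BH-adjust the tested p-values."""
    stats = aggregate_sites(psms)
    by_site: dict[str, list[SiteReplicateStat]] = {}
    for s in stats:
        by_site.setdefault(s.site, []).append(s)
    results = [combine_test(group, z_cutoff, method) for group in by_site.values()]
    tested = [r for r in results if not math.isnan(r.p_value)]
    if tested:
        qvals = multipletests([r.p_value for r in tested], method="fdr_bh")[1]
        for r, q in zip(tested, qvals):
            r.q_value = float(q)
    return sorted(results, key=lambda r: r.site)


def read_psm_table(path: str | Path, proteins: dict[str, str] | None = None) -> list[PsmRecord]:
    """Read a PSM TSV.

    Required columns: ``peptide``, ``modifications`` (``Phospho [S3(100)]``
    dialect), ``master_proteins`` (semicolon-delimited accessions),
    ``abundance_control``, ``abundance_treatment``, ``replicate``.  An
    optional ``peptide_start`` column (semicolon-delimited, one per master)
    supplies peptide positions; otherwise they are located in the supplied
    protein sequences.
    """
    tab = pd.read_csv(path, sep="\t", comment="#")
    required = {"peptide", "modifications", "master_proteins",
                "abundance_control", "abundance_treatment", "replicate"}
    if not required <= set(tab.columns):
        raise PhosphoError(f"PSM table must have columns {sorted(required)}")
    psms = []
    for row in tab.itertuples(index=False):
        masters = [a.strip() for a in str(row.master_proteins).split(";") if a.strip()]
        if "peptide_start" in tab.columns and not pd.isna(row.peptide_start):
            starts_list = [int(x) for x in str(row.peptide_start).split(";")]
            starts = dict(zip(masters, starts_list))
        elif proteins is not None:
            starts = compute_peptide_starts(row.peptide, masters, proteins)
        else:
            raise PhosphoError(
                "PSM table lacks peptide_start column and no protein FASTA given"
            )
        psms.append(
            PsmRecord(
                peptide=row.peptide,
                modification=parse_modification(row.modifications),
                master_proteins=masters,
                abundance_control=float(row.abundance_control),
                abundance_treatment=float(row.abundance_treatment),
                replicate=int(row.replicate),
                peptide_start=starts,
                preceding=getattr(row, "preceding", "") or "",
                following=getattr(row, "following", "") or "",
            )
        )
    return psms


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Load protein sequences keyed by the first word of each header."""
    proteins: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name:
                    proteins[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name:
        proteins[name] = "".join(chunks)
    return proteins


def results_to_frame(results: list[SiteTestResult],
                     stats: list[SiteReplicateStat] | None = None) -> pd.DataFrame:
    by_site: dict[str, dict[int, SiteReplicateStat]] = {}
    for s in stats or []:
        by_site.setdefault(s.site, {})[s.replicate] = s
    rows = []
    for r in results:
        row = {"site": r.site, "k": r.k, "combined_z": r.combined_z,
               "p_value": r.p_value, "q_value": r.q_value,
               "direction": r.direction, "mean_log_ratio": r.mean_log_ratio,
               "n_replicates_flagged": sum(r.per_replicate_flags.values())}
        for rep, s in sorted(by_site.get(r.site, {}).items()):
            row[f"log_ratio_rep{rep}"] = s.log_ratio
            row[f"z_rep{rep}"] = s.z
        rows.append(row)
    return pd.DataFrame(rows)
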