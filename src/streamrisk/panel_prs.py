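"""Hardy-Weinberg-normalized multiplicative polygenic risk scores.

Each SNP in a panel carries a published per-allele odds ratio ``OR`` and a
risk-allele frequency ``p``.  Under Hardy-Weinberg equilibrium the three
genotypes (0, 1 or 2 copies of the risk allele) occur with frequencies
``(1-p)^2``, ``2p(1-p)`` and ``p^2``, so the unscaled population-average
risk is

    mu = (1 - p)^2 + 2 p (1 - p) OR + p^2 OR^2

Dividing the genotype relative risks ``1, OR, OR^2`` by ``mu`` centres them
so that the population-average adjusted risk is exactly 1.  A subject's
polygenic risk score (PRS) is the product of adjusted risks across the
panel, which assumes the SNPs act independently and additively on the
log-odds scale; the PRS is therefore itself a relative risk with population
average 1 and can multiply any baseline hazard directly.

SNPs are taken as linkage-independent: no pruning or correlation
adjustment is performed here, so callers must supply panels of
approximately independent markers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger("streamrisk.panel_prs")

PANEL_COLUMNS = ["rsid", "risk_allele", "other_allele", "or_per_allele", "risk_allele_freq"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpDescriptor:
    """A single panel SNP: published odds ratio and risk-allele frequency."""

    rsid: str
    risk_allele: str
    or_per_allele: float
    risk_allele_freq: float
    other_allele: str | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("SNP descriptor requires a non-empty rsid")
        if not (math.isfinite(self.or_per_allele) and self.or_per_allele > 0):
            raise ValidationError(
                f"{self.rsid}: or_per_allele must be a positive finite number, "
                f"got {self.or_per_allele!r}"
            )
        if not (0.0 <= self.risk_allele_freq <= 1.0):
            raise ValidationError(
                f"{self.rsid}: risk_allele_freq must lie in [0, 1], "
                f"got {self.risk_allele_freq!r}"
            )

    @property
    def mu(self) -> float:
        """HWE population-average unscaled risk for this SNP."""
        return snp_mu(self.or_per_allele, self.risk_allele_freq)


@dataclass(frozen=True)
class SnpPanel:
    """An ordered, rsid-unique collection of SNP descriptors for one ethnicity."""

    snps: tuple[SnpDescriptor, ...]
    ethnicity_label: str = ""
    version: str = ""

    def __post_init__(self) -> None:
        if not self.snps:
            raise ValidationError("a SNP panel must contain at least one SNP")
        object.__setattr__(self, "snps", tuple(self.snps))
        rsids = [s.rsid for s in self.snps]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise ValidationError(f"duplicate rsids in panel: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self) -> Iterator[SnpDescriptor]:
        return iter(self.snps)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self.snps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [s.rsid for s in self.snps],
                "risk_allele": [s.risk_allele for s in self.snps],
                "other_allele": [s.other_allele or "" for s in self.snps],
                "or_per_allele": [s.or_per_allele for s in self.snps],
                "risk_allele_freq": [s.risk_allele_freq for s in self.snps],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, ethnicity_label: str = "", version: str = ""
    ) -> "SnpPanel":
        """Read a panel CSV with header
        ``rsid,risk_allele,other_allele,or_per_allele,risk_allele_freq``."""
        df = pd.read_csv(path, dtype={"rsid": str})
        missing = {"rsid", "risk_allele", "or_per_allele", "risk_allele_freq"} - set(df.columns)
        if missing:
            raise ValidationError(
                f"panel file {path} lacks required columns: {', '.join(sorted(missing))}"
            )
        snps = tuple(
            SnpDescriptor(
                rsid=row.rsid,
                risk_allele=str(row.risk_allele),
                other_allele=(str(row.other_allele) or None)
                if "other_allele" in df.columns and pd.notna(row.other_allele)
                else None,
                or_per_allele=float(row.or_per_allele),
                risk_allele_freq=float(row.risk_allele_freq),
            )
            for row in df.itertuples()
        )
        return cls(snps=snps, ethnicity_label=ethnicity_label, version=version)


@dataclass
class GenotypeVector:
    """Risk-allele counts for one subject, keyed by rsid.

    Missing genotypes are represented by absent keys or ``None`` values.
    """

    subject_id: str
    counts: Mapping[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rsid, c in self.counts.items():
            if c is None:
                continue
            if isinstance(c, float) and math.isnan(c):
                continue
            if c not in (0, 1, 2):
                raise ValidationError(
                    f"subject {self.subject_id}, {rsid}: risk-allele count must be "
                    f"0, 1 or 2, got {c!r}"
                )

    def count(self, rsid: str) -> int | None:
        c = self.counts.get(rsid)
        if c is None or (isinstance(c, float) and math.isnan(c)):
            return None
        return int(c)


@dataclass(frozen=True)
class PrsScore:
    """A subject's multiplicative PRS (population average 1)."""

    subject_id: str
    value: float
    n_missing: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value) and self.value > 0):
            raise ValidationError(
                f"subject {self.subject_id}: PRS must be positive and finite, "
                f"got {self.value!r}"
            )


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def snp_mu(or_per_allele: float, freq: float, rsid: str | None = None) -> float:
    """HWE-weighted population-average risk mu = (1-p)^2 + 2p(1-p) OR + p^2 OR^2.

    mu is the mean of the genotype relative risks {1, OR, OR^2} under the
    Hardy-Weinberg genotype distribution at risk-allele frequency p.
    """
    tag = f"{rsid}: " if rsid else ""
    if not (math.isfinite(or_per_allele) and or_per_allele > 0):
        raise ValidationError(f"{tag}or_per_allele must be positive, got {or_per_allele!r}")
    if not (0.0 <= freq <= 1.0):
        raise ValidationError(f"{tag}risk_allele_freq must lie in [0, 1], got {freq!r}")
    q = 1.0 - freq
    return q * q + 2.0 * freq * q * or_per_allele + freq * freq * or_per_allele**2


def genotype_adjusted_risk(snp: SnpDescriptor, count: int) -> float:
    """Adjusted relative risk OR^count / mu for a genotype with ``count``
    risk alleles; the HWE-weighted mean over the three genotypes is 1."""
    if count not in (0, 1, 2):
        raise ValidationError(
            f"{snp.rsid}: risk-allele count must be 0, 1 or 2, got {count!r}"
        )
    return snp.or_per_allele**count / snp.mu


def log_adjusted_risk_table(panel: SnpPanel) -> np.ndarray:
    """Per-SNP log adjusted risks, shape (n_snps, 3): entry [i, g] is
    ``g * log(OR_i) - log(mu_i)``."""
    log_or = np.log([s.or_per_allele for s in panel])
    log_mu = np.log([s.mu for s in panel])
    counts = np.arange(3)[None, :]
    return counts * log_or[:, None] - log_mu[:, None]


def compute_prs(
    genotype: GenotypeVector,
    panel: SnpPanel,
    missing_policy: str = "population_mean",
    max_missing_frac: float = 0.1,
) -> PrsScore:
    """Multiply adjusted genotype risks across the panel.

    The product is accumulated as a sum of logs to avoid underflow on large
    panels.  Under ``missing_policy='population_mean'`` a missing genotype
    contributes the population-average factor 1 and increments ``n_missing``
    (a warning is logged when more than ``max_missing_frac`` of the panel is
    missing); under ``'error'`` any missing genotype raises, listing the
    rsids.  Genotyped rsids absent from the panel are logged and ignored.
    """
    if missing_policy not in ("population_mean", "error"):
        raise ValidationError(
            f"unknown missing_policy {missing_policy!r}; "
            "expected 'population_mean' or 'error'"
        )
    panel_rsids = set(panel.rsids)
    extra = sorted(set(genotype.counts) - panel_rsids)
    if extra:
        logger.warning(
            "subject %s: %d genotyped rsids not in panel ignored (%s%s)",
            genotype.subject_id,
            len(extra),
            ", ".join(extra[:5]),
            ", ..." if len(extra) > 5 else "",
        )

    log_sum = 0.0
    missing: list[str] = []
    for snp in panel:
        c = genotype.count(snp.rsid)
        if c is None:
            missing.append(snp.rsid)
            continue
        log_sum += c * math.log(snp.or_per_allele) - math.log(snp.mu)

    if missing and missing_policy == "error":
        raise ValidationError(
            f"subject {genotype.subject_id}: missing genotypes for "
            f"{len(missing)} panel SNPs: {', '.join(missing)}"
        )
    if len(missing) > max_missing_frac * len(panel):
        logger.warning(
            "subject %s: %d/%d panel SNPs missing (> %.0f%% threshold); "
            "PRS uses population-average factors for the gaps",
            genotype.subject_id, len(missing), len(panel), 100 * max_missing_frac,
        )
    return PrsScore(
        subject_id=genotype.subject_id,
        value=math.exp(log_sum),
        n_missing=len(missing),
    )


def compute_prs_matrix(
    counts: np.ndarray, panel: SnpPanel
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized PRS for a (n_subjects, n_snps) count matrix.

    Column order must match the panel.  Missing genotypes are encoded as -1
    (or any negative value) and contribute the population-average factor 1,
    as under ``missing_policy='population_mean'``.  Returns
    ``(values, n_missing)`` arrays of length n_subjects.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] != len(panel):
        raise ValidationError(
            f"count matrix must have shape (n_subjects, {len(panel)}), "
            f"got {counts.shape}"
        )
    valid = counts >= 0
    if not np.all((counts[valid] >= 0) & (counts[valid] <= 2)):
        raise ValidationError("risk-allele counts must be 0, 1 or 2 (or negative = missing)")
    table = log_adjusted_risk_table(panel)  # (k, 3)
    idx = np.clip(counts, 0, 2).astype(np.intp)
    logs = table[np.arange(len(panel))[None, :], idx]
    logs = np.where(valid, logs, 0.0)
    return np.exp(logs.sum(axis=1)), (~valid).sum(axis=1)


# ---------------------------------------------------------------------------
# Genotype I/O
# ---------------------------------------------------------------------------

def read_genotypes_csv(path: str | Path) -> list[GenotypeVector]:
    """Read wide-format genotypes: ``subject_id,<rsid1>,<rsid2>,...`` with
    cells in {0, 1, 2}; empty cells mean missing."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValidationError(f"genotype file {path} lacks a subject_id column")
    rsids = [c for c in df.columns if c != "subject_id"]
    out = []
    for row in df.itertuples(index=False):
        counts: dict[str, int | None] = {}
        for rsid, value in zip(rsids, row[1:]):
            if pd.isna(value):
                counts[rsid] = None
            else:
                counts[rsid] = int(value)
        out.append(GenotypeVector(subject_id=row.subject_id, counts=counts))
    return out


def write_genotypes_csv(
    genotypes: Sequence[GenotypeVector], rsids: Sequence[str], path: str | Path
) -> None:
    records = []
    for g in genotypes:
        rec: dict[str, object] = {"subject_id": g.subject_id}
        for rsid in rsids:
            c = g.count(rsid)
            rec[rsid] = "" if c is None else c
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def genotypes_from_vcf(path: str | Path, panel: SnpPanel) -> list[GenotypeVector]:
    """Convert VCF GT fields to risk-allele counts for the panel's rsids.

    Variants are matched on the ID column; the panel's stated risk allele
    must equal REF or one of the ALT alleles.  Strand flips are NOT
    auto-resolved — a risk allele matching neither REF nor ALT raises,
    because silently flipping strands corrupts scores.
    """
    from cyvcf2 import VCF  # deferred: only needed for VCF ingestion

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    counts: dict[str, dict[str, int | None]] = {s: {} for s in samples}
    panel_map = {s.rsid: s for s in panel}
    seen: set[str] = set()
    for variant in vcf:
        snp = panel_map.get(variant.ID)
        if snp is None:
            continue
        seen.add(variant.ID)
        alleles = [variant.REF] + list(variant.ALT)
        if snp.risk_allele not in alleles:
            raise ValidationError(
                f"{snp.rsid}: risk allele {snp.risk_allele} matches neither REF "
                f"({variant.REF}) nor ALT ({','.join(variant.ALT) or '-'}); "
                "strand flips are not auto-resolved"
            )
        target = alleles.index(snp.risk_allele)
        for sample, gt in zip(samples, variant.genotypes):
            pair = gt[:2]
            if any(a < 0 for a in pair):
                counts[sample][snp.rsid] = None
            else:
                counts[sample][snp.rsid] = sum(1 for a in pair if a == target)
    unseen = set(panel.rsids) - seen
    if unseen:
        logger.warning(
            "%d panel rsids absent from VCF %s; their genotypes are missing",
            len(unseen), path,
        )
    return [GenotypeVector(subject_id=s, counts=counts[s]) for s in samples]
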