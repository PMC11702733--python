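"""Readers, writers, and harmonization for PRS-related tabular formats.

Supported formats
-----------------
* variant weight files: PGS-Catalog scoring dialect ('#' metadata header,
  ``rsID``/``effect_allele``/``effect_weight`` columns) and a plain TSV
  dialect (``variant_id``/``effect_allele``/``other_allele``/``weight``);
* ancestry-specific allele-frequency panels (one frequency column per
  ancestry);
* global ancestry proportion tables (ADMIXTURE/RFMix Q-style);
* RFMix msp-style local-ancestry interval files;
* genotypes as VCF (GT or DS) or as a plain dosage matrix.

All in-memory containers are thin dataclasses over numpy arrays with
validation on construction, so downstream numerical code can assume
clean inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class FormatError(ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class ValidationError(ValueError):
    """Parsed values violate a container invariant (e.g. duplicate ids)."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class WeightSet:
    """A PRS definition: variants, effect alleles, and fixed per-allele weights.

    Weights are additive effects per copy of ``effect_allele`` and are
    treated as fixed, known constants throughout the framework.
    """

    variant_id: np.ndarray
    effect_allele: np.ndarray
    weight: np.ndarray
    other_allele: np.ndarray | None = None
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.effect_allele = np.asarray(self.effect_allele, dtype=object)
        self.weight = np.asarray(self.weight, dtype=float)
        if self.other_allele is not None:
            self.other_allele = np.asarray(self.other_allele, dtype=object)
        p = len(self.variant_id)
        if len(self.effect_allele) != p or len(self.weight) != p:
            raise ValidationError("weight-set columns have inconsistent lengths")
        if len(np.unique(self.variant_id)) != p:
            dup = pd.Series(self.variant_id)
            dup = dup[dup.duplicated()].iloc[0]
            raise ValidationError(f"duplicate variant_id: {dup!r}")
        if not np.all(np.isfinite(self.weight)):
            raise ValidationError("weights must be finite")
        if self.other_allele is not None:
            same = self.effect_allele == self.other_allele
            if np.any(same):
                bad = self.variant_id[same][0]
                raise ValidationError(
                    f"effect_allele equals other_allele for variant {bad!r}"
                )

    @property
    def n_variants(self) -> int:
        return len(self.variant_id)

    def subset(self, index: np.ndarray) -> "WeightSet":
        """Return a new :class:`WeightSet` restricted/reordered by ``index``."""
        take = lambda a: None if a is None else a[index]
        return WeightSet(
            variant_id=self.variant_id[index],
            effect_allele=self.effect_allele[index],
            weight=self.weight[index],
            other_allele=take(self.other_allele),
            chrom=take(self.chrom),
            pos=take(self.pos),
        )


@dataclass
class AncestryFrequencyPanel:
    """Per-variant, per-ancestry frequencies of a counted allele.

    ``freq`` has shape ``(p, K)``; ``ancestries`` names its columns in
    order.  Frequencies refer to ``counted_allele``; :func:`harmonize`
    aligns this with a weight set's effect alleles.
    """

    variant_id: np.ndarray
    counted_allele: np.ndarray
    ancestries: list[str]
    freq: np.ndarray

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.counted_allele = np.asarray(self.counted_allele, dtype=object)
        self.ancestries = list(self.ancestries)
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 2:
            raise ValidationError("freq must be a 2-d (variants x ancestries) array")
        if len(self.ancestries) < 1:
            raise ValidationError("at least one ancestry required")
        if len(set(self.ancestries)) != len(self.ancestries):
            raise ValidationError("ancestry names must be unique")
        if self.freq.shape != (len(self.variant_id), len(self.ancestries)):
            raise ValidationError("freq shape inconsistent with ids/ancestries")
        if np.any((self.freq < 0) | (self.freq > 1) | ~np.isfinite(self.freq)):
            bad = np.argwhere((self.freq < 0) | (self.freq > 1))[0]
            raise ValidationError(
                f"frequency outside [0,1] at variant row {bad[0]}, "
                f"ancestry {self.ancestries[bad[1]]!r}"
            )

    @property
    def n_variants(self) -> int:
        return len(self.variant_id)

    @property
    def n_ancestries(self) -> int:
        return len(self.ancestries)

    def subset(self, index: np.ndarray) -> "AncestryFrequencyPanel":
        return AncestryFrequencyPanel(
            variant_id=self.variant_id[index],
            counted_allele=self.counted_allele[index],
            ancestries=self.ancestries,
            freq=self.freq[index],
        )


@dataclass
class GlobalAncestryMatrix:
    """Global ancestry proportions: one row per individual, K columns summing to 1."""

    individual_id: np.ndarray
    ancestries: list[str]
    props: np.ndarray

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.ancestries = list(self.ancestries)
        self.props = np.asarray(self.props, dtype=float)
        if self.props.shape != (len(self.individual_id), len(self.ancestries)):
            raise ValidationError("props shape inconsistent with ids/ancestries")
        if np.any(self.props < 0):
            raise ValidationError("negative ancestry proportion")
        sums = self.props.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            i = int(np.argmax(np.abs(sums - 1.0)))
            raise ValidationError(
                f"row for {self.individual_id[i]!r} sums to {sums[i]:.8f}, not 1"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_id)


@dataclass
class LocalAncestryTensor:
    """Per-individual, per-variant, per-haplotype ancestry labels.

    ``codes`` has shape ``(n, p, 2)`` with integer codes into ``ancestries``.
    """

    individual_id: np.ndarray
    variant_id: np.ndarray
    ancestries: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.ancestries = list(self.ancestries)
        self.codes = np.asarray(self.codes)
        if self.codes.shape != (len(self.individual_id), len(self.variant_id), 2):
            raise ValidationError("codes must have shape (n, p, 2)")
        if self.codes.min(initial=0) < 0 or self.codes.max(initial=0) >= len(
            self.ancestries
        ):
            raise ValidationError("ancestry code outside the declared ancestry set")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_id)

    @property
    def n_variants(self) -> int:
        return len(self.variant_id)

    def subset_variants(self, index: np.ndarray) -> "LocalAncestryTensor":
        return LocalAncestryTensor(
            individual_id=self.individual_id,
            variant_id=self.variant_id[index],
            ancestries=self.ancestries,
            codes=self.codes[:, index, :],
        )


@dataclass
class GenotypeMatrix:
    """Allele counts (dosages) per individual x variant; NaN marks missing."""

    individual_id: np.ndarray
    variant_id: np.ndarray
    dosage: np.ndarray
    counted_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.counted_allele is not None:
            self.counted_allele = np.asarray(self.counted_allele, dtype=object)
        if self.dosage.shape != (len(self.individual_id), len(self.variant_id)):
            raise ValidationError("dosage shape inconsistent with ids")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if np.any(bad & ~np.isnan(self.dosage)):
            raise ValidationError("dosages must lie in [0, 2] (or NaN for missing)")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_id)

    @property
    def n_variants(self) -> int:
        return len(self.variant_id)

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            individual_id=self.individual_id,
            variant_id=self.variant_id[index],
            dosage=self.dosage[:, index],
            counted_allele=None
            if self.counted_allele is None
            else self.counted_allele[index],
        )


@dataclass
class HarmonizationReport:
    """Bookkeeping from :func:`harmonize`."""

    n_kept: int
    n_flipped: int
    n_dropped: int
    dropped: list = field(default_factory=list)
    ambiguous: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Weight files
# ---------------------------------------------------------------------------

_PGS_COLUMNS = {"rsID": "variant_id", "effect_allele": "effect_allele",
                "other_allele": "other_allele", "effect_weight": "weight",
                "chr_name": "chrom", "chr_position": "pos"}
_PLAIN_COLUMNS = {"variant_id": "variant_id", "effect_allele": "effect_allele",
                  "other_allele": "other_allele", "weight": "weight",
                  "chrom": "chrom", "pos": "pos"}


def read_weight_file(path, dialect: str = "plain_tsv") -> WeightSet:
    """Read a variant weight file.

    Parameters
    ----------
    path : str or path-like
        Tab-separated file.  Lines starting ``#`` are metadata and skipped.
    dialect : {"plain_tsv", "pgs_catalog"}
        Column naming convention.  The PGS-Catalog dialect uses ``rsID``,
        ``effect_allele``, ``other_allele``, ``effect_weight``.
    """
    if dialect == "pgs_catalog":
        colmap = _PGS_COLUMNS
        required = ("rsID", "effect_allele", "effect_weight")
    elif dialect == "plain_tsv":
        colmap = _PLAIN_COLUMNS
        required = ("variant_id", "effect_allele", "weight")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    df = df.rename(columns=colmap)
    kwargs = {}
    for name in ("other_allele", "chrom", "pos"):
        if name in df.columns:
            kwargs[name] = df[name].to_numpy(dtype=object)
    if "pos" in kwargs:
        kwargs["pos"] = np.asarray(kwargs["pos"], dtype=float).astype(int)
    return WeightSet(
        variant_id=df["variant_id"].to_numpy(dtype=object),
        effect_allele=df["effect_allele"].to_numpy(dtype=object),
        weight=df["weight"].to_numpy(dtype=float),
        **kwargs,
    )


def write_weight_file(weights: WeightSet, path, dialect: str = "plain_tsv") -> None:
    """Write a weight set; inverse of :func:`read_weight_file`."""
    data = {"variant_id": weights.variant_id,
            "effect_allele": weights.effect_allele,
            "weight": weights.weight}
    if weights.other_allele is not None:
        data["other_allele"] = weights.other_allele
    if weights.chrom is not None:
        data["chrom"] = weights.chrom
    if weights.pos is not None:
        data["pos"] = weights.pos
    df = pd.DataFrame(data)
    if dialect == "pgs_catalog":
        inv = {v: k for k, v in _PGS_COLUMNS.items()}
        df = df.rename(columns=inv)
        with open(path, "w") as fh:
            fh.write("### PGS scoring file dialect\n")
            df.to_csv(fh, sep="\t", index=False)
    elif dialect == "plain_tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Frequency panels
# ---------------------------------------------------------------------------


def read_frequency_panel(path) -> AncestryFrequencyPanel:
    """Read a TSV frequency panel: variant_id, counted_allele, one column
    per ancestry (file column order defines the ancestry order)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"variant_id": str})
    for col in ("variant_id", "counted_allele"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    ancestries = [c for c in df.columns if c not in ("variant_id", "counted_allele")]
    if not ancestries:
        raise FormatError(f"no ancestry frequency columns in {path}")
    freq = df[ancestries].to_numpy(dtype=float)
    bad = np.argwhere((freq < 0) | (freq > 1) | ~np.isfinite(freq))
    if bad.size:
        # +2: header line plus 1-based numbering
        raise ValidationError(
            f"frequency outside [0,1] at line {bad[0][0] + 2} of {path}"
        )
    return AncestryFrequencyPanel(
        variant_id=df["variant_id"].to_numpy(dtype=object),
        counted_allele=df["counted_allele"].to_numpy(dtype=object),
        ancestries=ancestries,
        freq=freq,
    )


def write_frequency_panel(panel: AncestryFrequencyPanel, path) -> None:
    df = pd.DataFrame({"variant_id": panel.variant_id,
                       "counted_allele": panel.counted_allele})
    for k, name in enumerate(panel.ancestries):
        df[name] = panel.freq[:, k]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Global ancestry (Q-style) tables
# ---------------------------------------------------------------------------


def read_global_ancestry(path, renormalize_tol: float = 1e-3) -> GlobalAncestryMatrix:
    """Read a Q-style proportions table (individual_id + one column per ancestry).

    Rows whose proportions sum to 1 within ``renormalize_tol`` are rescaled
    to sum exactly to 1; larger deviations raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"individual_id": str})
    if "individual_id" not in df.columns:
        raise FormatError(f"missing required column 'individual_id' in {path}")
    ancestries = [c for c in df.columns if c != "individual_id"]
    props = df[ancestries].to_numpy(dtype=float)
    if np.any(props < 0):
        raise ValidationError("negative ancestry proportion")
    sums = props.sum(axis=1)
    off = np.abs(sums - 1.0)
    if np.any(off > renormalize_tol):
        i = int(np.argmax(off))
        raise ValidationError(
            f"row {i} sums to {sums[i]:.6f}; deviation exceeds tol {renormalize_tol}"
        )
    props = props / sums[:, None]
    return GlobalAncestryMatrix(
        individual_id=df["individual_id"].to_numpy(dtype=object),
        ancestries=ancestries,
        props=props,
    )


def write_global_ancestry(gam: GlobalAncestryMatrix, path) -> None:
    df = pd.DataFrame({"individual_id": gam.individual_id})
    for k, name in enumerate(gam.ancestries):
        df[name] = gam.props[:, k]
    df.to_csv(path, sep="\t", index=False)


def rescale_dropping_ancestry(gam: GlobalAncestryMatrix, drop: str) -> GlobalAncestryMatrix:
    """Remove one ancestry column and renormalize the remaining proportions.

    Used when a low-level ancestry component (e.g. a trace reference
    population) is excluded: each retained proportion is divided by the
    row sum of the retained ancestries so rows again sum to 1.
    """
    if drop not in gam.ancestries:
        raise ValueError(f"{drop!r} is not a declared ancestry")
    keep = [k for k, a in enumerate(gam.ancestries) if a != drop]
    retained = gam.props[:, keep]
    sums = retained.sum(axis=1)
    if np.any(sums <= 0):
        i = int(np.argmin(sums))
        raise ValidationError(
            f"individual {gam.individual_id[i]!r} has zero retained ancestry; "
            "rescale undefined"
        )
    return GlobalAncestryMatrix(
        individual_id=gam.individual_id,
        ancestries=[gam.ancestries[k] for k in keep],
        props=retained / sums[:, None],
    )


# ---------------------------------------------------------------------------
# RFMix msp-style local ancestry
# ---------------------------------------------------------------------------


def read_local_ancestry_msp(path, variant_positions, variant_ids=None) -> LocalAncestryTensor:
    """Map variant positions onto an msp-style local-ancestry interval file.

    The file carries a first line ``#Subpopulation order/codes: NAME=0 ...``,
    a header line ``#chm spos epos sgpos egpos n snps <ind>.0 <ind>.1 ...``,
    and one row per ancestry-switch interval.  Intervals are 0-based
    half-open ``[spos, epos)``.

    Parameters
    ----------
    variant_positions : sequence of int
        Positions to look up (same coordinate system as the file).
    variant_ids : sequence of str, optional
        Names for the returned variants; defaults to ``pos<position>``.
    """
    positions = np.asarray(list(variant_positions), dtype=int)
    with open(path) as fh:
        legend_line = fh.readline().strip()
        header_line = fh.readline().strip()
        body = pd.read_csv(fh, sep="\t", header=None)
    if not legend_line.startswith("#Subpopulation order/codes:"):
        raise FormatError("msp file must start with a '#Subpopulation order/codes:' line")
    legend = {}
    for tok in legend_line.split(":", 1)[1].split():
        name, _, code = tok.partition("=")
        legend[int(code)] = name
    ancestries = [legend[c] for c in sorted(legend)]
    header = header_line.lstrip("#").split("\t")
    hap_cols = header[6:]
    if len(hap_cols) % 2 != 0:
        raise FormatError("odd number of haplotype columns in msp header")
    individuals = [c[:-2] for c in hap_cols[::2]]
    body.columns = header
    spos = body["spos"].to_numpy(dtype=int)
    epos = body["epos"].to_numpy(dtype=int)
    hap_codes = body[hap_cols].to_numpy(dtype=int)  # (n_intervals, 2n)

    order = np.argsort(spos)
    spos, epos, hap_codes = spos[order], epos[order], hap_codes[order]
    # locate the covering interval for each position (half-open [spos, epos))
    idx = np.searchsorted(spos, positions, side="right") - 1
    uncovered = (idx < 0) | (positions >= epos[np.clip(idx, 0, None)])
    if np.any(uncovered):
        missing = positions[uncovered].tolist()
        raise FormatError(f"positions not covered by any msp interval: {missing}")
    per_pos = hap_codes[idx]  # (p, 2n)
    n = len(individuals)
    p = len(positions)
    codes = per_pos.reshape(p, n, 2).transpose(1, 0, 2)
    if variant_ids is None:
        variant_ids = [f"pos{q}" for q in positions]
    return LocalAncestryTensor(
        individual_id=np.asarray(individuals, dtype=object),
        variant_id=np.asarray(list(variant_ids), dtype=object),
        ancestries=ancestries,
        codes=codes.astype(np.int8),
    )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes as ALT-allele counts (VCF) or a dosage matrix (TSV).

    VCF records use GT when present, else DS.  Multiallelic records are
    skipped with a logged warning; missing genotypes become NaN.  Dosage
    TSV headers may declare the counted allele as ``variant:ALLELE``.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    ids, alts, cols = [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning(
                "skipping multiallelic record %s:%s (%d ALT alleles)",
                rec.CHROM, rec.POS, len(rec.ALT),
            )
            continue
        vid = rec.ID if rec.ID not in (None, ".") else (
            f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        )
        gt = np.asarray(rec.genotypes, dtype=float)[:, :2]
        counts = np.where((gt < 0).any(axis=1), np.nan, (gt > 0).sum(axis=1))
        if np.isnan(counts).all():
            ds = rec.format("DS")
            if ds is not None:
                counts = np.asarray(ds, dtype=float).ravel()
        ids.append(vid)
        alts.append(rec.ALT[0])
        cols.append(counts)
    if not ids:
        raise FormatError(f"no usable biallelic records in {path}")
    return GenotypeMatrix(
        individual_id=samples,
        variant_id=np.asarray(ids, dtype=object),
        dosage=np.column_stack(cols),
        counted_allele=np.asarray(alts, dtype=object),
    )


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"individual_id": str})
    if "individual_id" not in df.columns:
        raise FormatError(f"missing required column 'individual_id' in {path}")
    raw = [c for c in df.columns if c != "individual_id"]
    ids, alleles = [], []
    for c in raw:
        vid, _, allele = c.partition(":")
        ids.append(vid)
        alleles.append(allele if allele else None)
    counted = None
    if all(a is not None for a in alleles):
        counted = np.asarray(alleles, dtype=object)
    return GenotypeMatrix(
        individual_id=df["individual_id"].to_numpy(dtype=object),
        variant_id=np.asarray(ids, dtype=object),
        dosage=df[raw].to_numpy(dtype=float),
        counted_allele=counted,
    )


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    cols = {}
    for j, vid in enumerate(genotypes.variant_id):
        name = vid
        if genotypes.counted_allele is not None:
            name = f"{vid}:{genotypes.counted_allele[j]}"
        cols[name] = genotypes.dosage[:, j]
    df = pd.DataFrame({"individual_id": genotypes.individual_id, **cols})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def harmonize(
    weights: WeightSet,
    panel: AncestryFrequencyPanel,
    genotypes: GenotypeMatrix | None = None,
):
    """Align a weight set, frequency panel, and (optionally) genotypes.

    Restricts all sources to their common variants, in the weight file's
    order, and re-expresses panel frequencies (and genotype dosages) as
    counts of each variant's *effect* allele:

    * panel counted allele == effect allele: kept as-is;
    * panel counted allele == other allele: frequency flipped ``f -> 1-f``;
    * otherwise the variant is dropped and reported.

    Strand-ambiguous (A/T, C/G) variants are matched by id only and kept
    with a logged warning; no strand inference is attempted.

    Returns ``(weights, panel, genotypes, report)``; ``genotypes`` is None
    when not supplied.  The operation is idempotent.
    """
    panel_index = {v: j for j, v in enumerate(panel.variant_id)}
    geno_index = (
        {v: j for j, v in enumerate(genotypes.variant_id)}
        if genotypes is not None
        else None
    )

    keep_w, keep_p, keep_g = [], [], []
    flip_freq, flip_geno = [], []
    report = HarmonizationReport(0, 0, 0)
    for i, vid in enumerate(weights.variant_id):
        j = panel_index.get(vid)
        if j is None:
            continue
        if geno_index is not None:
            gj = geno_index.get(vid)
            if gj is None:
                continue
        ea = weights.effect_allele[i]
        oa = weights.other_allele[i] if weights.other_allele is not None else None
        ca = panel.counted_allele[j]
        if oa is not None and (ea, oa) in _AMBIGUOUS_PAIRS:
            logger.warning("strand-ambiguous variant %s kept, matched by id", vid)
            report.ambiguous.append(vid)
        if ca == ea:
            flip = False
        elif oa is not None and ca == oa:
            flip = True
        else:
            report.n_dropped += 1
            report.dropped.append(vid)
            continue
        keep_w.append(i)
        keep_p.append(j)
        flip_freq.append(flip)
        if geno_index is not None:
            keep_g.append(gj)
            if genotypes.counted_allele is None:
                flip_geno.append(False)  # assume effect-allele dosages
            else:
                gca = genotypes.counted_allele[gj]
                if gca == ea:
                    flip_geno.append(False)
                elif oa is not None and gca == oa:
                    flip_geno.append(True)
                else:
                    # genotype allele irreconcilable: drop the variant
                    keep_w.pop(); keep_p.pop(); flip_freq.pop(); keep_g.pop()
                    report.n_dropped += 1
                    report.dropped.append(vid)

    if not keep_w:
        raise ValidationError("no variants shared between weight set and panel")

    w = weights.subset(np.asarray(keep_w, dtype=int))
    pnl = panel.subset(np.asarray(keep_p, dtype=int))
    flip_freq = np.asarray(flip_freq, dtype=bool)
    pnl = replace(
        pnl,
        freq=np.where(flip_freq[:, None], 1.0 - pnl.freq, pnl.freq),
        counted_allele=w.effect_allele.copy(),
    )
    geno = None
    if genotypes is not None:
        geno = genotypes.subset_variants(np.asarray(keep_g, dtype=int))
        fg = np.asarray(flip_geno, dtype=bool)
        geno = replace(
            geno,
            dosage=np.where(fg[None, :], 2.0 - geno.dosage, geno.dosage),
            counted_allele=w.effect_allele.copy(),
        )
    report.n_kept = len(keep_w)
    report.n_flipped = int(flip_freq.sum())
    return w, pnl, geno, report
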