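"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
* internal: 0-based half-open ``[start, end)``
* calls TSV and PLINK ``.cnv``: 1-based inclusive (``start-1, end`` on read)
* BED (masks, genes): 0-based half-open, kept as-is

The conversion is an exact bijection: internal length equals
``file_end - file_start + 1`` for the 1-based inclusive dialects.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

from .core import (
    Algorithm,
    CnvCall,
    CnvState,
    GeneModel,
    GenomicInterval,
    MaskName,
    Phenotype,
    RegionMask,
    SampleRecord,
    normalize_chrom,
    state_from_copy_number,
)

logger = logging.getLogger(__name__)

CALL_TSV_COLUMNS = [
    "sample_id", "chrom", "start", "end", "state",
    "copy_number", "n_probes", "confidence", "algorithm",
]

_STATE_TOKENS = {
    "del": CnvState.DEL, "deletion": CnvState.DEL, "loss": CnvState.DEL,
    "dup": CnvState.DUP, "duplication": CnvState.DUP, "gain": CnvState.DUP,
}

_ALGO_TOKENS = {a.value.lower(): a for a in Algorithm}


class FormatError(ValueError):
    """A malformed record in an external file; message names the line."""


def _parse_state(token: str, line_no: int, path: str) -> tuple[CnvState, int | None]:
    """Interpret a state token: del/dup word or an integer copy number."""
    tok = token.strip().lower()
    if tok in _STATE_TOKENS:
        return _STATE_TOKENS[tok], None
    try:
        cn = int(tok)
    except ValueError:
        raise FormatError(
            f"{path}:{line_no}: unknown state token {token!r}"
        ) from None
    try:
        return state_from_copy_number(cn), cn
    except ValueError as exc:
        raise FormatError(f"{path}:{line_no}: {exc}") from None


def _parse_algorithm(token: str, line_no: int, path: str) -> Algorithm:
    algo = _ALGO_TOKENS.get(token.strip().lower())
    if algo is None:
        raise FormatError(f"{path}:{line_no}: unknown algorithm {token!r}")
    return algo


def read_calls(
    path: str | Path,
    dialect: str = "tsv",
    algorithm: Algorithm | None = None,
) -> list[CnvCall]:
    """Read per-algorithm CNV calls from a TSV or PLINK ``.cnv`` file.

    Parameters
    ----------
    dialect
        ``"tsv"`` (header with named columns) or ``"plink_cnv"``
        (``FID IID CHR BP1 BP2 TYPE SCORE SITES``, whitespace separated).
    algorithm
        Required for the PLINK dialect, which does not carry the source
        algorithm; ignored for TSV.

    File coordinates are 1-based inclusive and are converted to the internal
    0-based half-open convention.  Rows on chromosome Y or MT are skipped with
    a warning; any other malformed row raises :class:`FormatError` naming the
    line number.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_calls_tsv(path)
    if dialect == "plink_cnv":
        if algorithm is None:
            raise ValueError("PLINK .cnv dialect requires an explicit algorithm")
        return _read_calls_plink(path, algorithm)
    raise ValueError(f"unknown dialect {dialect!r}")


def _convert_coords(start_s: str, end_s: str, line_no: int, path: str) -> tuple[int, int]:
    try:
        start_1based, end_incl = int(start_s), int(end_s)
    except ValueError:
        raise FormatError(f"{path}:{line_no}: non-integer coordinates") from None
    if end_incl < start_1based:
        raise FormatError(f"{path}:{line_no}: end < start")
    return start_1based - 1, end_incl


def _read_calls_tsv(path: Path) -> list[CnvCall]:
    calls: list[CnvCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(CALL_TSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            try:
                chrom = normalize_chrom(row["chrom"])
            except ValueError as exc:
                logger.warning("%s:%d: skipped (%s)", path, line_no, exc)
                continue
            start, end = _convert_coords(row["start"], row["end"], line_no, str(path))
            state, cn_from_state = _parse_state(row["state"], line_no, str(path))
            cn_field = row.get("copy_number", "").strip()
            copy_number = int(cn_field) if cn_field not in ("", "NA", ".") else cn_from_state
            try:
                calls.append(
                    CnvCall(
                        sample_id=row["sample_id"],
                        interval=GenomicInterval(chrom, start, end),
                        state=state,
                        copy_number=copy_number,
                        n_probes=int(row["n_probes"]),
                        confidence=float(row["confidence"]),
                        algorithm=_parse_algorithm(row["algorithm"], line_no, str(path)),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from None
    return calls


def _read_calls_plink(path: Path, algorithm: Algorithm) -> list[CnvCall]:
    calls: list[CnvCall] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if fields[0].upper() == "FID":  # optional header
                continue
            if len(fields) < 8:
                raise FormatError(f"{path}:{line_no}: expected 8 fields, got {len(fields)}")
            _fid, iid, chrom_s, bp1, bp2, type_s, score, sites = fields[:8]
            try:
                chrom = normalize_chrom(chrom_s)
            except ValueError as exc:
                logger.warning("%s:%d: skipped (%s)", path, line_no, exc)
                continue
            start, end = _convert_coords(bp1, bp2, line_no, str(path))
            try:
                cn = int(type_s)
            except ValueError:
                raise FormatError(f"{path}:{line_no}: non-integer TYPE {type_s!r}") from None
            try:
                state = state_from_copy_number(cn)
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from None
            try:
                calls.append(
                    CnvCall(
                        sample_id=iid,
                        interval=GenomicInterval(chrom, start, end),
                        state=state,
                        copy_number=cn,
                        n_probes=int(sites),
                        confidence=float(score),
                        algorithm=algorithm,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from None
    return calls


def write_calls(calls: list[CnvCall], path: str | Path, dialect: str = "tsv") -> Path:
    """Write calls in a dialect readable by :func:`read_calls` (exact round-trip)."""
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(CALL_TSV_COLUMNS)
            for c in calls:
                writer.writerow([
                    c.sample_id, c.interval.chrom,
                    c.interval.start + 1, c.interval.end,
                    c.state.value.lower(),
                    c.copy_number if c.copy_number is not None else "NA",
                    c.n_probes, _fmt_float(c.confidence), c.algorithm.value,
                ])
    elif dialect == "plink_cnv":
        with open(path, "w") as fh:
            fh.write("FID IID CHR BP1 BP2 TYPE SCORE SITES\n")
            for c in calls:
                cn = c.copy_number
                if cn is None:
                    cn = 1 if c.state is CnvState.DEL else 3
                fh.write(
                    f"{c.sample_id} {c.sample_id} {c.interval.chrom} "
                    f"{c.interval.start + 1} {c.interval.end} {cn} "
                    f"{_fmt_float(c.confidence)} {c.n_probes}\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def _fmt_float(x: float) -> str:
    return f"{x:g}"


def read_mask(path: str | Path, name: MaskName = MaskName.CUSTOM) -> RegionMask:
    """Read a BED3+ file into a merged, sorted :class:`RegionMask`."""
    path = Path(path)
    regions: list[GenomicInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{line_no}: BED needs >= 3 columns")
            try:
                chrom = normalize_chrom(fields[0])
            except ValueError as exc:
                logger.warning("%s:%d: skipped (%s)", path, line_no, exc)
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{line_no}: non-integer coordinates") from None
            regions.append(GenomicInterval(chrom, start, end))
    return RegionMask.from_intervals(name, regions)


def write_mask(mask: RegionMask, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in mask.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
    return path


_PHENOTYPE_TOKENS = {
    "1": Phenotype.CONTROL, "2": Phenotype.CASE,
    "control": Phenotype.CONTROL, "case": Phenotype.CASE,
}


def read_samples(path: str | Path) -> list[SampleRecord]:
    """Read the sample metadata TSV (phenotype coded 1=control, 2=case)."""
    path = Path(path)
    samples: list[SampleRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "phenotype", "call_rate", "lrr_sd", "baf_sd", "wave_factor"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            pheno = _PHENOTYPE_TOKENS.get(row["phenotype"].strip().lower())
            if pheno is None:
                raise FormatError(
                    f"{path}:{line_no}: unknown phenotype {row['phenotype']!r}"
                )
            try:
                samples.append(
                    SampleRecord(
                        sample_id=row["sample_id"],
                        phenotype=pheno,
                        sex=row.get("sex", "unknown"),
                        call_rate=float(row["call_rate"]),
                        lrr_sd=float(row["lrr_sd"]),
                        baf_sd=float(row["baf_sd"]),
                        wave_factor=float(row["wave_factor"]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from None
    return samples


def write_samples(samples: list[SampleRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["sample_id", "phenotype", "sex", "call_rate", "lrr_sd", "baf_sd", "wave_factor"]
        )
        for s in samples:
            writer.writerow([
                s.sample_id, "2" if s.phenotype is Phenotype.CASE else "1", s.sex,
                _fmt_float(s.call_rate), _fmt_float(s.lrr_sd),
                _fmt_float(s.baf_sd), _fmt_float(s.wave_factor),
            ])
    return path


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (exon blocks) or a 4-column BED (span only)."""
    path = Path(path)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{line_no}: gene BED needs >= 4 columns")
            try:
                chrom = normalize_chrom(fields[0])
            except ValueError as exc:
                logger.warning("%s:%d: skipped (%s)", path, line_no, exc)
                continue
            start, end, name = int(fields[1]), int(fields[2]), fields[3]
            span = GenomicInterval(chrom, start, end)
            exons: tuple[GenomicInterval, ...] = ()
            if len(fields) >= 12:
                block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
                if len(block_sizes) != len(block_starts):
                    raise FormatError(f"{path}:{line_no}: BED12 block count mismatch")
                exons = tuple(
                    GenomicInterval(chrom, start + off, start + off + size)
                    for off, size in zip(block_starts, block_sizes)
                )
            genes.append(GeneModel(gene_name=name, span=span, exons=exons))
    return genes


def write_genes(genes: list[GeneModel], path: str | Path) -> Path:
    """Write gene models as BED12."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons or (g.span,)
            sizes = ",".join(str(e.length()) for e in exons) + ","
            starts = ",".join(str(e.start - g.span.start) for e in exons) + ","
            fh.write(
                f"{g.span.chrom}\t{g.span.start}\t{g.span.end}\t{g.gene_name}"
                f"\t0\t+\t{g.span.start}\t{g.span.end}\t0\t{len(exons)}"
                f"\t{sizes}\t{starts}\n"
            )
    return path
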