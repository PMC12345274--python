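"""Readers and writers for the standard formats the pipeline touches.

GFF3 annotation, BED/narrowPeak ChIP peaks, FPKM matrices (TSV), promoter
FASTA, ortholog maps, GO annotation tables, metabolite feature tables and
compound libraries, plus Cytoscape-importable network exports (GraphML,
SIF, edge TSV).

Internal coordinate convention: 0-based half-open everywhere. GFF3
(1-based inclusive) is converted on read and on write; BED passes through.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import gffutils
import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, NsdgrnError, Peak

logger = logging.getLogger("nsdgrn.io")

PathLike = Union[str, Path]

NETWORK_FORMATS = ("graphml", "sif", "tsv")


# ---------------------------------------------------------------------------
# annotation (GFF3)
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r"(?:^|;)ID=([^;\n]+)")


def read_annotation(path: PathLike) -> List[GeneModel]:
    """Parse a GFF3 file into an ordered list of :class:`GeneModel`.

    One record per ``gene`` feature. The translation start is taken from
    the first CDS base in transcription order when CDS features exist
    (searching children at any nesting depth, so CDS under mRNA works);
    otherwise the gene's 5' end is used as a documented fallback.

    Raises on duplicate gene IDs (naming the ID) and on missing strand.
    """
    path = Path(path)
    _check_duplicate_gene_ids(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    genes: List[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.strand not in ("+", "-"):
            raise NsdgrnError(
                f"{path.name}: gene {feat.id!r} has missing/invalid strand {feat.strand!r}"
            )
        start0 = feat.start - 1
        end0 = feat.end
        cds = list(db.children(feat, featuretype="CDS"))
        if cds:
            if feat.strand == "+":
                translation_start = min(c.start for c in cds) - 1
            else:
                translation_start = max(c.end for c in cds) - 1
        else:
            translation_start = start0 if feat.strand == "+" else end0 - 1
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=start0,
                end=end0,
                strand=feat.strand,
                translation_start=translation_start,
            )
        )
    logger.info("read_annotation: %d genes from %s", len(genes), path)
    return genes


def _check_duplicate_gene_ids(path: Path) -> None:
    seen: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            m = _GENE_ID_RE.search(fields[8])
            if m:
                gid = m.group(1)
                seen[gid] = seen.get(gid, 0) + 1
    dupes = sorted(g for g, n in seen.items() if n > 1)
    if dupes:
        raise NsdgrnError(f"{path.name}: duplicate gene ID(s): {', '.join(dupes)}")


def write_annotation(genes: Sequence[GeneModel], path: PathLike, source: str = "nsdgrn") -> None:
    """Write genes as GFF3 (gene + one CDS child carrying the translation start)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        source,
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )
            # CDS spans from the translation start to the gene's 3' end
            if g.strand == "+":
                cds_start1, cds_end1 = g.translation_start + 1, g.end
            else:
                cds_start1, cds_end1 = g.start + 1, g.translation_start + 1
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        source,
                        "CDS",
                        str(cds_start1),
                        str(cds_end1),
                        ".",
                        g.strand,
                        "0",
                        f"ID=cds-{g.gene_id};Parent={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# peaks (BED / narrowPeak)
# ---------------------------------------------------------------------------


def read_peaks(path: PathLike) -> List[Peak]:
    """Parse a BED or narrowPeak file into an ordered list of :class:`Peak`.

    Coordinates pass through unchanged (BED is already 0-based half-open).
    The summit is ``start + offset`` when a narrowPeak summit-offset column
    (column 10) is present and non-negative, else the interval midpoint
    (floor). Rows with start >= end are a hard error naming the line.
    """
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise NsdgrnError(
                    f"{Path(path).name}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise NsdgrnError(f"{Path(path).name}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise NsdgrnError(
                    f"{Path(path).name}:{lineno}: start >= end ({start} >= {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"peak_{lineno}"
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            summit = (start + end) // 2
            if len(fields) >= 10:  # narrowPeak: column 10 is the summit offset
                try:
                    offset = int(fields[9])
                except ValueError:
                    offset = -1
                if offset >= 0:
                    summit = start + offset
            peaks.append(Peak(chrom=chrom, start=start, end=end, summit=summit,
                              name=name, score=score))
    logger.info("read_peaks: %d peaks from %s", len(peaks), path)
    return peaks


def write_peaks(peaks: Sequence[Peak], path: PathLike, fmt: str = "bed") -> None:
    """Write peaks as BED6 or narrowPeak (summit emitted as an offset)."""
    if fmt not in ("bed", "narrowPeak"):
        raise NsdgrnError(f"unknown peak format {fmt!r}; supported: bed, narrowPeak")
    with open(path, "w") as fh:
        for p in peaks:
            score = "0" if p.score is None else f"{p.score:g}"
            row = [p.chrom, str(p.start), str(p.end), p.name, score, "."]
            if fmt == "narrowPeak":
                row += ["0", "-1", "-1", str(p.summit - p.start)]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# expression matrices & generic tables
# ---------------------------------------------------------------------------


def read_expression(path: PathLike) -> pd.DataFrame:
    """Read a genes x samples FPKM TSV (first column gene_id, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()[:10]
        raise NsdgrnError(f"{Path(path).name}: duplicate gene ids: {dupes}")
    if (df.to_numpy() < 0).any():
        raise NsdgrnError(f"{Path(path).name}: negative FPKM values")
    return df


def write_expression(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_set(path: PathLike) -> List[str]:
    """One gene id per line (first tab-separated field); '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0])
    return out


def write_gene_set(genes: Iterable[str], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_ortholog_map(path: PathLike) -> List[Tuple[str, str]]:
    """Two-column TSV of (species-A id, species-B id) pairs, order preserved."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise NsdgrnError(f"{Path(path).name}:{lineno}: expected two columns")
            pairs.append((fields[0], fields[1]))
    return pairs


def write_ortholog_map(pairs: Iterable[Tuple[str, str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_go_annotation(path: PathLike) -> pd.DataFrame:
    """GO annotation TSV with columns gene, term and optionally name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "term" not in cols:
        raise NsdgrnError(f"{Path(path).name}: expected 'gene' and 'term' columns")
    rename = {cols["gene"]: "gene", cols["term"]: "term"}
    if "name" in cols:
        rename[cols["name"]] = "name"
    df = df.rename(columns=rename)
    if "name" not in df.columns:
        df["name"] = df["term"]
    return df[["gene", "term", "name"]]


def read_feature_table(path: PathLike) -> pd.DataFrame:
    """Metabolite feature TSV: feature_id, mz, rt, then per-sample intensities."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("mz", "rt"):
        if col not in df.columns:
            raise NsdgrnError(f"{Path(path).name}: missing column {col!r}")
    return df


def write_feature_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_compound_library(path: PathLike) -> pd.DataFrame:
    """Compound library TSV: compound, mass, optional rt (reference retention time)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "compound" not in cols or "mass" not in cols:
        raise NsdgrnError(f"{Path(path).name}: expected 'compound' and 'mass' columns")
    df = df.rename(columns={cols["compound"]: "compound", cols["mass"]: "mass"})
    if "rt" in cols:
        df = df.rename(columns={cols["rt"]: "rt"})
    else:
        df["rt"] = float("nan")
    if (df["mass"] <= 0).any():
        raise NsdgrnError(f"{Path(path).name}: non-positive compound mass")
    return df[["compound", "mass", "rt"]]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read sequences as an id -> uppercase string mapping (order preserved)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------


def write_network(grn: nx.Graph, path: PathLike, fmt: str = "graphml") -> None:
    """Export a network for Cytoscape.

    * ``graphml`` -- full attribute round-trip (origin, category, is_seed,
      kind, confidence, direct).
    * ``sif``     -- 'a pp b' for PPI edges, 'regulator reg target' for
      direct-binding edges; isolated nodes emitted as single-token lines.
    * ``tsv``     -- edge table with attribute columns.
    """
    if fmt not in NETWORK_FORMATS:
        raise NsdgrnError(
            f"unknown network format {fmt!r}; supported: {', '.join(NETWORK_FORMATS)}"
        )
    g = grn.copy()
    for u, v, data in g.edges(data=True):
        data["direct"] = data.get("kind") == "direct_binding"
    if fmt == "graphml":
        nx.write_graphml(g, str(path), named_key_ids=True)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, data in sorted(g.edges(data=True)):
                label = "reg" if data.get("kind") == "direct_binding" else "pp"
                fh.write(f"{u}\t{label}\t{v}\n")
            for node in sorted(g.nodes):
                if g.degree(node) == 0:
                    fh.write(f"{node}\n")
    else:  # tsv
        rows = []
        for u, v, data in sorted(g.edges(data=True)):
            rows.append(
                {
                    "source": u,
                    "target": v,
                    "kind": data.get("kind", "ppi"),
                    "confidence": data.get("confidence", ""),
                    "direct": data.get("direct", False),
                }
            )
        pd.DataFrame(
            rows, columns=["source", "target", "kind", "confidence", "direct"]
        ).to_csv(path, sep="\t", index=False)


def read_network(path: PathLike) -> nx.Graph:
    """Read a GraphML network written by :func:`write_network`."""
    return nx.read_graphml(str(path), node_type=str)
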