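"""Genome region maps, mutation-class assignment, and interval arithmetic.

The genome is partitioned into the strata used throughout the analysis:
autosomes, the X pseudoautosomal region (PAR), the X-unique region, CpG
islands (CGI), and CGIs hypomethylated in sperm (HMR_CGI) versus the
remainder (NONHMR_CGI = CGI minus HMR_CGI).  Intervals are 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from canidnm.records import MUTATION_CLASSES

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_mutation(context3: str, ref: str, alt: str) -> str:
    """Assign the strand-collapsed 7-class label of a single-base change.

    The six base classes (C>A, C>G, C>T, T>A, T>C, T>G) are collapsed to
    the pyrimidine strand; C>T inside a CpG dinucleotide (on either
    strand) is split out as ``CpG>TpG``.

    Parameters
    ----------
    context3 : str
        Reference triplet centred on the mutated base.
    ref, alt : str
        Reference and alternate alleles; ``ref`` must equal the centre
        of ``context3``.
    """
    context3, ref, alt = context3.upper(), ref.upper(), alt.upper()
    if len(context3) != 3 or any(b not in "ACGT" for b in context3):
        raise ValueError(f"context must be an ACGT triplet, got {context3!r}")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"ref/alt must be single ACGT bases, got {ref!r}>{alt!r}")
    if context3[1] != ref:
        # accept a context given on the opposite strand
        if _revcomp(context3)[1] == ref:
            context3 = _revcomp(context3)
        else:
            raise ValueError(f"ref {ref!r} does not match context centre {context3[1]!r}")
    if ref == alt:
        raise ValueError("ref == alt is not a mutation")
    if ref in "AG":  # collapse to pyrimidine strand
        context3, ref, alt = _revcomp(context3), _revcomp(ref), _revcomp(alt)
    if ref == "C" and alt == "T" and context3[2] == "G":
        return "CpG>TpG"
    return f"{ref}>{alt}"


# ---------------------------------------------------------------------------
# interval arithmetic on (start, end) half-open pairs

def merge_intervals(intervals):
    """Sort and merge overlapping/adjacent half-open intervals."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = np.asarray(sorted(map(tuple, intervals)), dtype=np.int64)
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def subtract_intervals(a, b):
    """Set difference a \\ b for merged half-open interval arrays."""
    a, b = merge_intervals(a), merge_intervals(b)
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def total_span(intervals) -> int:
    iv = merge_intervals(intervals)
    return int((iv[:, 1] - iv[:, 0]).sum()) if len(iv) else 0


@dataclass
class GenomeRegionMap:
    """Labeled genomic intervals plus contig bounds, with fast lookup.

    ``intervals`` maps label -> {contig -> (n, 2) int array}, 0-based
    half-open, merged.  ``x_contig`` names the X chromosome; PAR and
    X_UNIQUE must partition it.  Lookup returns a unique primary
    category (PAR > X_UNIQUE on X, otherwise AUTOSOME) plus CGI / HMR
    flags.
    """

    contigs: dict  # name -> length
    intervals: dict = field(default_factory=dict)  # label -> {contig -> ndarray}
    x_contig: str = "X"

    def __post_init__(self):
        self._validate()

    def _iv(self, label, contig):
        return self.intervals.get(label, {}).get(contig, np.empty((0, 2), dtype=np.int64))

    def _validate(self):
        for label, per_contig in self.intervals.items():
            for contig, iv in per_contig.items():
                if contig not in self.contigs:
                    raise ValueError(f"{label}: unknown contig {contig!r}")
                iv = merge_intervals(iv)
                per_contig[contig] = iv
                if len(iv) and (iv[0, 0] < 0 or iv[-1, 1] > self.contigs[contig]):
                    raise ValueError(
                        f"{label} interval beyond contig {contig} bounds "
                        f"(length {self.contigs[contig]})"
                    )
        for contig in self.intervals.get("PAR", {}):
            if contig != self.x_contig:
                raise ValueError(f"PAR declared on non-X contig {contig!r}")
        # PAR and X_UNIQUE partition X with no overlap
        if self.x_contig in self.contigs:
            par = self._iv("PAR", self.x_contig)
            xu = self._iv("X_UNIQUE", self.x_contig)
            both = total_span(np.vstack([par, xu])) if (len(par) or len(xu)) else 0
            if total_span(par) + total_span(xu) != both:
                raise ValueError("PAR and X_UNIQUE overlap on the X contig")
        # HMR_CGI ⊆ CGI; NONHMR_CGI derived
        nonhmr = {}
        for contig in self.intervals.get("CGI", {}):
            cgi = self._iv("CGI", contig)
            hmr = self._iv("HMR_CGI", contig)
            if total_span(subtract_intervals(hmr, cgi)) != 0:
                raise ValueError(f"HMR_CGI not contained in CGI on {contig}")
            diff = subtract_intervals(cgi, hmr)
            if len(diff):
                nonhmr[contig] = diff
        for contig in self.intervals.get("HMR_CGI", {}):
            if contig not in self.intervals.get("CGI", {}):
                raise ValueError(f"HMR_CGI on {contig} without CGI annotation")
        self.intervals["NONHMR_CGI"] = nonhmr

    def _contains(self, label, contig, pos) -> bool:
        iv = self._iv(label, contig)
        if not len(iv):
            return False
        i = np.searchsorted(iv[:, 0], pos, side="right") - 1
        return i >= 0 and pos < iv[i, 1]

    def primary_category(self, contig: str, pos: int) -> str:
        """Unique primary category of a position: PAR > X_UNIQUE > AUTOSOME."""
        if contig not in self.contigs:
            raise KeyError(f"unknown contig {contig!r}")
        if not 0 <= pos < self.contigs[contig]:
            raise ValueError(f"position {pos} outside contig {contig}")
        if contig == self.x_contig:
            if self._contains("PAR", contig, pos):
                return "PAR"
            return "X_UNIQUE"
        return "AUTOSOME"

    def region_flags(self, contig: str, pos: int) -> tuple:
        """(primary category, in_CGI, in_HMR_CGI) for a position."""
        primary = self.primary_category(contig, pos)
        in_cgi = self._contains("CGI", contig, pos)
        in_hmr = in_cgi and self._contains("HMR_CGI", contig, pos)
        return primary, in_cgi, in_hmr

    def span(self, label: str) -> int:
        """Total bp covered by a label (AUTOSOME = non-X contig lengths)."""
        cache = self.__dict__.setdefault("_span_cache", {})
        if label not in cache:
            if label == "AUTOSOME":
                cache[label] = sum(
                    l for c, l in self.contigs.items() if c != self.x_contig
                )
            else:
                # intervals are merged at construction time
                cache[label] = sum(
                    int((iv[:, 1] - iv[:, 0]).sum())
                    for iv in self.intervals.get(label, {}).values()
                )
        return cache[label]

    def genome_size(self) -> int:
        return sum(self.contigs.values())


def read_bed(path) -> dict:
    """Read a BED file (0-based half-open) into {contig -> (n,2) array}."""
    per_contig: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: need at least 3 BED columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            per_contig.setdefault(contig, []).append((start, end))
    return {c: merge_intervals(iv) for c, iv in per_contig.items()}


def read_region_map(bed_paths: dict, contig_table, x_contig: str = "X") -> GenomeRegionMap:
    """Build a :class:`GenomeRegionMap` from per-label BED files.

    Parameters
    ----------
    bed_paths : dict
        Maps labels (subset of PAR, X_UNIQUE, CGI, HMR_CGI) to BED paths.
    contig_table
        Path to a two-column TSV (contig, length) or a dict.
    """
    if isinstance(contig_table, dict):
        contigs = dict(contig_table)
    else:
        df = pd.read_csv(contig_table, sep="\t", header=None, comment="#",
                         names=["contig", "length"], dtype={"contig": str})
        contigs = dict(zip(df.contig, df.length.astype(int)))
    intervals = {label: read_bed(path) for label, path in bed_paths.items()}
    # X_UNIQUE defaults to X minus PAR when not given explicitly
    if x_contig in contigs and "X_UNIQUE" not in intervals:
        whole_x = np.array([[0, contigs[x_contig]]], dtype=np.int64)
        par = intervals.get("PAR", {}).get(x_contig, np.empty((0, 2), dtype=np.int64))
        intervals["X_UNIQUE"] = {x_contig: subtract_intervals(whole_x, par)}
    return GenomeRegionMap(contigs=contigs, intervals=intervals, x_contig=x_contig)


def write_results(tables: dict, path, fmt: str = "TSV") -> None:
    """Write result tables to TSV (one file per table) or a single JSON.

    Floats survive a round trip to 12 significant digits.
    """
    import json
    import os

    if fmt.upper() == "TSV":
        os.makedirs(path, exist_ok=True)
        for name, df in tables.items():
            pd.DataFrame(df).to_csv(
                os.path.join(path, f"{name}.tsv"), sep="\t", index=False,
                float_format="%.12g",
            )
    elif fmt.upper() == "JSON":
        payload = {
            name: pd.DataFrame(df).to_dict(orient="list") for name, df in tables.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)
    else:
        raise ValueError(f"unknown format {fmt!r}")
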