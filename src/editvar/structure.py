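"""IRAlu hairpin structure and the structural impact of SNP alleles.

Inverted Alu repeats (IRAlus) in a transcript fold into long double-stranded
hairpins, the preferred ADAR substrate. This module pairs each edited Alu
with its closest oppositely oriented neighbour, folds the resulting sequence,
and quantifies how the two alleles of a SNP perturb the structure relative to
the editing site: shortest spatial distance in the structure graph, change in
the number of paired bases, and change in the folding score. Distributions of
these metrics are compared between SNP classes (significant association vs
control) with two-sample Kolmogorov-Smirnov tests.

Two folding engines are available. The default internal engine is a weighted
Nussinov dynamic program (G-C = 3, A-U = 2, G-U wobble = 1, minimum hairpin
loop 3) with the additional rule that a G-U pair may not terminate a helix:
every wobble pair must be stacked directly between two other pairs. The
external engine shells out to the RNAfold command (run with ``--noClosingGU``)
and returns the thermodynamic minimum-free-energy structure; the score metric
label records which engine produced a structure.
"""

from __future__ import annotations

import shutil
import subprocess
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .errors import DataError, ParameterError, UntestableError

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_NEG = -1e9

# pair weights, indexed by base codes (A,C,G,U)
_WEIGHT = np.zeros((4, 4))
_WEIGHT[2, 1] = _WEIGHT[1, 2] = 3.0          # G-C
_WEIGHT[0, 3] = _WEIGHT[3, 0] = 2.0          # A-U
_WEIGHT[2, 3] = _WEIGHT[3, 2] = 1.0          # G-U wobble
_WC = np.zeros((4, 4), dtype=bool)
_WC[2, 1] = _WC[1, 2] = _WC[0, 3] = _WC[3, 0] = True


def encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in sequence.upper()], dtype=np.int8)
    except KeyError as exc:
        raise DataError(f"invalid nucleotide {exc.args[0]!r} in sequence") from exc


@dataclass
class HairpinStructure:
    sequence: str
    pairing: np.ndarray          # partner index per position, -1 if unpaired
    score: float                 # folding objective (weighted pairs or MFE)
    metric: str                  # "weighted_pairs" | "mfe_kcal_mol"

    def __post_init__(self):
        self.pairing = np.asarray(self.pairing, dtype=np.int64)
        p = self.pairing
        idx = np.flatnonzero(p >= 0)
        if np.any(p[idx] == idx):
            raise DataError("a position cannot pair with itself")
        if not np.all(p[p[idx]] == idx):
            raise DataError("pairing is not an involution")

    @property
    def n_pairs(self) -> int:
        return int(np.count_nonzero(self.pairing >= 0) // 2)

    @property
    def dot_bracket(self) -> str:
        out = []
        for i, j in enumerate(self.pairing):
            out.append("." if j < 0 else ("(" if j > i else ")"))
        return "".join(out)


def _fold_tables(codes: np.ndarray, min_loop: int):
    n = codes.size
    M = np.zeros((n, n))
    Pin = np.full((n, n), _NEG)
    Pout = np.full((n, n), _NEG)
    for d in range(min_loop + 1, n):
        for i in range(n - d):
            j = i + d
            w = _WEIGHT[codes[i], codes[j]]
            if w > 0:
                inner_free = M[i + 1, j - 1] if d >= 2 else 0.0
                inner_stack = Pin[i + 1, j - 1]
                if _WC[codes[i], codes[j]]:
                    Pin[i, j] = Pout[i, j] = w + max(inner_free, inner_stack)
                elif inner_stack > _NEG / 2:           # G-U must stack inward
                    Pin[i, j] = w + inner_stack
            # bifurcation: j paired with some k in [i, j - min_loop - 1]
            best = M[i, j - 1]
            kmax = j - min_loop - 1
            if kmax >= i:
                ks = np.arange(i, kmax + 1)
                left = np.empty(ks.size)
                left[0] = 0.0
                if ks.size > 1:
                    left[1:] = M[i, ks[1:] - 1]
                cand = left + Pout[ks, j]
                best = max(best, cand.max())
            M[i, j] = best
    return M, Pin, Pout


def _traceback(codes, M, Pin, Pout, min_loop):
    n = codes.size
    pairing = np.full(n, -1, dtype=np.int64)
    stack = [("M", 0, n - 1)]
    tol = 1e-9
    while stack:
        state, i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        if state == "M":
            if M[i, j] <= tol:
                continue
            if abs(M[i, j] - M[i, j - 1]) < tol:
                stack.append(("M", i, j - 1))
                continue
            kmax = j - min_loop - 1
            for k in range(i, kmax + 1):
                left = 0.0 if k == i else M[i, k - 1]
                if abs(M[i, j] - (left + Pout[k, j])) < tol:
                    if k > i:
                        stack.append(("M", i, k - 1))
                    stack.append(("P", k, j))
                    break
        else:  # a pair (i, j); Pin and Pout agree wherever both defined
            w = _WEIGHT[codes[i], codes[j]]
            pairing[i], pairing[j] = j, i
            val = max(Pin[i, j], Pout[i, j])
            if abs(val - (w + Pin[i + 1, j - 1])) < tol \
                    and Pin[i + 1, j - 1] > _NEG / 2:
                stack.append(("P", i + 1, j - 1))
            else:
                stack.append(("M", i + 1, j - 1))
    return pairing


def fold(sequence: str, mode: str = "internal",
         min_loop: int = 3) -> HairpinStructure:
    """Predict the secondary structure of ``sequence`` (RNA or DNA alphabet).

    ``mode='internal'`` runs the weighted Nussinov dynamic program described
    in the module docstring; ``mode='external'`` delegates to the RNAfold
    executable with ``--noClosingGU`` and reports the minimum free energy as
    the (negative-valued) score.
    """
    if mode == "external":
        return fold_external(sequence)
    if mode != "internal":
        raise ParameterError(f"unknown fold mode {mode!r}")
    codes = encode(sequence)
    if codes.size < 2:
        return HairpinStructure(sequence, np.full(codes.size, -1), 0.0,
                                "weighted_pairs")
    M, Pin, Pout = _fold_tables(codes, min_loop)
    pairing = _traceback(codes, M, Pin, Pout, min_loop)
    return HairpinStructure(sequence, pairing, float(M[0, codes.size - 1]),
                            "weighted_pairs")


def fold_external(sequence: str, executable: str = "RNAfold") -> HairpinStructure:
    """Fold with the RNAfold command (``--noClosingGU``); requires the
    ViennaRNA suite on PATH."""
    encode(sequence)        # validate alphabet
    if shutil.which(executable) is None:
        raise ParameterError(f"{executable} not found on PATH")
    out = subprocess.run([executable, "--noClosingGU", "--noPS"],
                         input=sequence + "\n", capture_output=True,
                         text=True, check=True).stdout.splitlines()
    struct_line = out[1].strip()
    db = struct_line.split(" ")[0]
    energy = float(struct_line[struct_line.rfind("(") + 1:
                               struct_line.rfind(")")])
    return HairpinStructure(sequence, pairing_from_dot_bracket(db), energy,
                            "mfe_kcal_mol")


def pairing_from_dot_bracket(db: str) -> np.ndarray:
    pairing = np.full(len(db), -1, dtype=np.int64)
    stack = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pairing[i], pairing[j] = j, i
    return pairing


def structure_distance(structure: HairpinStructure, pos1: int, pos2: int) -> int:
    """Shortest-path distance between two positions in the structure graph
    whose edges are backbone adjacencies and base pairs."""
    n = len(structure.sequence)
    if not (0 <= pos1 < n and 0 <= pos2 < n):
        raise ParameterError("positions outside sequence")
    if pos1 == pos2:
        return 0
    pairing = structure.pairing
    dist = np.full(n, -1, dtype=np.int64)
    dist[pos1] = 0
    q = deque([pos1])
    while q:
        v = q.popleft()
        nbrs = [v - 1, v + 1]
        if pairing[v] >= 0:
            nbrs.append(int(pairing[v]))
        for u in nbrs:
            if 0 <= u < n and dist[u] < 0:
                dist[u] = dist[v] + 1
                if u == pos2:
                    return int(dist[u])
                q.append(u)
    return int(dist[pos2])


# ---- IRAlu geometry ---------------------------------------------------------

@dataclass
class IraluPair:
    """Two oppositely oriented Alu intervals forming an inverted repeat."""

    chrom: str
    alu1: tuple        # (start, end, strand), 1-based inclusive, genomic order
    alu2: tuple
    orientation_class: str            # "head-to-head" | "tail-to-tail"
    sequence: str = ""                # transcribed-sense sequence when extracted
    editing_offset: int = -1          # 0-based offsets into `sequence`
    snp_offset: int = -1


def find_iralu_partner(site_pos: int, chrom: str, alu_annotation: pd.DataFrame,
                       max_span: int = 20_000) -> IraluPair | None:
    """Pair the Alu containing an editing site with its nearest inverted
    neighbour.

    ``alu_annotation`` has 1-based inclusive columns chrom, start, end, strand,
    sorted by start. Returns None when the site is in no Alu or no
    opposite-strand neighbour lies within ``max_span`` of the host Alu
    (elements without a clear inverted partner are excluded from the
    analysis).
    """
    alus = alu_annotation[alu_annotation["chrom"] == chrom].reset_index(drop=True)
    host = alus[(alus["start"] <= site_pos) & (site_pos <= alus["end"])]
    if host.empty:
        return None
    host = host.iloc[0]
    others = alus[(alus["strand"] != host["strand"])
                  & ((alus["start"] > host["end"]) | (alus["end"] < host["start"]))]
    if others.empty:
        return None
    gap = np.where(others["start"] > host["end"],
                   others["start"] - host["end"],
                   host["start"] - others["end"])
    best = others.iloc[int(np.argmin(gap))]
    if gap.min() > max_span:
        return None
    left, right = (host, best) if host["start"] <= best["start"] else (best, host)
    # facing ends: + element has head at genomic start, tail at genomic end;
    # - element the reverse. left(+)/right(-) face tail|tail; left(-)/right(+)
    # face head|head.
    orientation = "tail-to-tail" if left["strand"] == "+" else "head-to-head"
    return IraluPair(
        chrom=chrom,
        alu1=(int(left["start"]), int(left["end"]), str(left["strand"])),
        alu2=(int(right["start"]), int(right["end"]), str(right["strand"])),
        orientation_class=orientation)


def extract_iralu_sequence(pair: IraluPair, fasta, site_pos: int,
                           snp_pos: int, sense_strand: str = "+") -> IraluPair:
    """Fill in the transcribed-sense sequence and offsets of an IRAlu pair.

    ``fasta`` is a pysam.FastaFile (or object with ``fetch(chrom, start0,
    end0)``); the sequence runs from the start of the left Alu to the end of
    the right one, reverse-complemented when the transcript is on ``-``.
    """
    start0 = pair.alu1[0] - 1
    end0 = pair.alu2[1]
    seq = fasta.fetch(pair.chrom, start0, end0).upper().replace("T", "U")
    off_site = site_pos - 1 - start0
    off_snp = snp_pos - 1 - start0
    if not (0 <= off_site < len(seq)) or not (0 <= off_snp < len(seq)):
        raise DataError("site or SNP outside the IRAlu span")
    if sense_strand == "-":
        comp = str.maketrans("ACGU", "UGCA")
        seq = seq.translate(comp)[::-1]
        off_site = len(seq) - 1 - off_site
        off_snp = len(seq) - 1 - off_snp
    pair.sequence = seq
    pair.editing_offset = off_site
    pair.snp_offset = off_snp
    return pair


@dataclass
class SnpStructureImpact:
    spatial_distance: int
    delta_pairs: int
    delta_score: float
    snp_class: str = "unclassified"   # "significant" | "control"
    snp_id: str = ""


def snp_structure_impact(pair: IraluPair, allele1_seq: str, allele2_seq: str,
                         mode: str = "internal",
                         snp_class: str = "unclassified") -> SnpStructureImpact:
    """Fold both allele sequences and measure the structural perturbation.

    ``delta_pairs`` and ``delta_score`` are allele2 minus allele1; the
    SNP-to-editing-site distance is measured on the allele-1 (reference)
    structure. The two sequences must differ at exactly the pair's SNP offset.
    """
    if len(allele1_seq) != len(allele2_seq):
        raise DataError("allele sequences must be equal length")
    diff = [i for i, (a, b) in enumerate(zip(allele1_seq, allele2_seq)) if a != b]
    if diff != [pair.snp_offset]:
        raise DataError(f"allele sequences must differ exactly at the SNP "
                        f"offset {pair.snp_offset}, differ at {diff}")
    s1 = fold(allele1_seq, mode=mode)
    s2 = fold(allele2_seq, mode=mode)
    return SnpStructureImpact(
        spatial_distance=structure_distance(s1, pair.snp_offset,
                                            pair.editing_offset),
        delta_pairs=s2.n_pairs - s1.n_pairs,
        delta_score=float(s2.score - s1.score),
        snp_class=snp_class)


def compare_impact_distributions(impacts) -> dict:
    """Two-sample KS comparison of |distance|, |delta_pairs| and |delta_score|
    between the significant and control SNP classes.

    Returns a dict metric -> {statistic, p_value, n_significant, n_control,
    cdf (DataFrame of pooled sorted values with per-class empirical CDFs)}.
    """
    sig = [x for x in impacts if x.snp_class == "significant"]
    ctl = [x for x in impacts if x.snp_class == "control"]
    if not sig or not ctl:
        raise UntestableError("both SNP classes must be non-empty")
    out = {}
    for metric in ("spatial_distance", "delta_pairs", "delta_score"):
        a = np.abs([getattr(x, metric) for x in sig]).astype(float)
        b = np.abs([getattr(x, metric) for x in ctl]).astype(float)
        ks = ks_2samp(a, b)
        grid = np.unique(np.concatenate([a, b]))
        cdf = pd.DataFrame({
            "value": grid,
            "cdf_significant": np.searchsorted(np.sort(a), grid, "right") / a.size,
            "cdf_control": np.searchsorted(np.sort(b), grid, "right") / b.size})
        out[metric] = {"statistic": float(ks.statistic),
                       "p_value": float(ks.pvalue),
                       "n_significant": a.size, "n_control": b.size,
                       "cdf": cdf}
    return out
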