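"""Scanning transcripts for canonical and bulged miRNA response elements (MREs).

Canonical site classes follow the standard seed-match taxonomy: a 6mer is the
reverse complement of miRNA seed positions 2-7, a 7mer-m8 extends pairing to
position 8, a 7mer-A1 adds an adenosine opposite miRNA position 1, and an 8mer
combines both. The *bulged* site class is a 6mer seed match with one extra
nucleotide inserted in the target strand (default at position 5 of the
7-nt motif, inserted base G/U/A), which creates a bulge in the duplex: the
miRNA still binds, but decay is not triggered — the hallmark of a sponge site.

All motif strings are canonicalised to target-strand 5'->3' sequences derived
from the miRNA by reverse complement; coordinates are 0-based half-open on the
sense strand. T and U are interchangeable on input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MIR16",
    "Mirna",
    "SiteHit",
    "reverse_complement",
    "canonical_site_strings",
    "find_canonical_sites",
    "find_bulged_sites",
    "bulged_site_strings",
    "duplex_score",
    "annotate_interactome",
    "hits_to_bed_frame",
]

_DNA_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
_RNA_COMP = str.maketrans("ACGUacgu", "UGCAugca")

#: duplex scoring weights: Watson-Crick pair, G:U wobble, mismatch, and the
#: penalty per unpaired (bulged) target base inside the duplex.
SCORE_WC = 2.0
SCORE_WOBBLE = 1.0
SCORE_MISMATCH = -1.0
BULGE_OPEN_PENALTY = 3.0

CANONICAL_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def reverse_complement(seq: str, alphabet: str = "DNA") -> str:
    """Watson-Crick reverse complement of ``seq`` (case preserved).

    ``alphabet`` is ``"DNA"`` (A/C/G/T) or ``"RNA"`` (A/C/G/U).
    """
    if alphabet not in ("DNA", "RNA"):
        raise ValueError(f"alphabet must be 'DNA' or 'RNA', got {alphabet!r}")
    valid = "ACGT" if alphabet == "DNA" else "ACGU"
    for i, ch in enumerate(seq):
        if ch.upper() not in valid:
            raise ValueError(
                f"invalid {alphabet} character {ch!r} at position {i}"
            )
    table = _DNA_COMP if alphabet == "DNA" else _RNA_COMP
    return seq.translate(table)[::-1]


@dataclass(frozen=True)
class Mirna:
    """A microRNA, 5'->3', with its seed window (1-based, inclusive start).

    The seed window [seed_start, seed_end] defines the core pairing region:
    the 6mer site complements positions seed_start..seed_end-1 (2-7 by
    default) and the 7mer-m8 site extends to seed_end (position 8).
    """

    name: str
    sequence: str
    seed_start: int = 2
    seed_end: int = 8

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        for i, ch in enumerate(seq):
            if ch not in "ACGU":
                raise ValueError(f"invalid RNA character {ch!r} at position {i}")
        if not (1 <= self.seed_start < self.seed_end <= len(seq)):
            raise ValueError(
                f"seed window {self.seed_start}:{self.seed_end} outside "
                f"miRNA of length {len(seq)}"
            )


#: hsa-miR-16-5p. Its seed (positions 2-7, AGCAGC) yields the 6mer target
#: motif GCTGCT; the bulged sponge motif is GCTG(G/T/A)CT.
MIR16 = Mirna("hsa-miR-16-5p", "UAGCAGCACGUAAAUAUUGGCG")


@dataclass(frozen=True)
class SiteHit:
    """A located binding site, 0-based half-open on the transcript sense strand."""

    transcript_id: str
    start: int
    end: int
    site_type: str                 # 6mer | 7mer-A1 | 7mer-m8 | 8mer | bulged
    inserted_base: str | None = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if (self.site_type == "bulged") != (self.inserted_base is not None):
            raise ValueError("inserted_base is set iff site_type is 'bulged'")


def _to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def canonical_site_strings(mirna: Mirna) -> dict[str, str]:
    """Target-strand 5'->3' DNA strings of the four canonical site classes."""
    m = mirna.sequence
    core = m[mirna.seed_start - 1 : mirna.seed_end - 1]   # positions 2-7
    ext = m[mirna.seed_start - 1 : mirna.seed_end]        # positions 2-8
    six = _to_dna(reverse_complement(core, "RNA"))
    m8 = _to_dna(reverse_complement(ext, "RNA"))
    return {
        "6mer": six,
        "7mer-m8": m8,
        "7mer-A1": six + "A",
        "8mer": m8 + "A",
    }


def bulged_site_strings(
    mirna: Mirna,
    bulge_position: int = 5,
    allowed_bases: Iterable[str] = ("G", "T", "A"),
) -> dict[str, str]:
    """Map inserted base -> 7-nt bulged motif (6mer with one insertion).

    ``bulge_position`` is 1-based within the 7-nt motif. C is excluded by
    default because an inserted C extends perfect pairing with miR-16 rather
    than creating a bulge.
    """
    six = canonical_site_strings(mirna)["6mer"]
    if not (1 < bulge_position <= len(six) + 1):
        raise ValueError(
            f"bulge_position must be in (1, {len(six) + 1}], got {bulge_position}"
        )
    motifs: dict[str, str] = {}
    for b in allowed_bases:
        bb = _to_dna(b)
        if bb not in "ACGT" or len(bb) != 1:
            raise ValueError(f"invalid inserted base {b!r}")
        motifs[bb] = six[: bulge_position - 1] + bb + six[bulge_position - 1 :]
    return motifs


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_canonical_sites(
    transcript: str,
    mirna: Mirna = MIR16,
    transcript_id: str = "",
) -> list[SiteHit]:
    """All canonical site occurrences, each locus reported once with its
    longest applicable class (8mer subsumes the 7mers, which subsume the 6mer).

    Overlapping *distinct* loci are all reported; hits are sorted
    left-to-right (then by decreasing length).
    """
    seq = _to_dna(transcript)
    strings = canonical_site_strings(mirna)
    raw: list[tuple[int, int, str]] = []
    for stype, s in strings.items():
        for p in _find_all(seq, s):
            raw.append((p, p + len(s), stype))
    hits = [
        (s, e, t)
        for (s, e, t) in raw
        if not any(
            (e2 - s2) > (e - s) and s2 <= s and e <= e2 for (s2, e2, _t2) in raw
        )
    ]
    hits.sort(key=lambda h: (h[0], -(h[1] - h[0])))
    return [
        SiteHit(
            transcript_id=transcript_id,
            start=s,
            end=e,
            site_type=t,
            score=duplex_score(mirna, seq[s:e]),
        )
        for (s, e, t) in hits
    ]


def find_bulged_sites(
    transcript: str,
    mirna: Mirna = MIR16,
    transcript_id: str = "",
    bulge_position: int = 5,
    allowed_bases: Iterable[str] = ("G", "T", "A"),
) -> list[SiteHit]:
    """All bulged (non-canonical) site occurrences.

    A bulged motif window that fully contains a canonical site is reported as
    canonical by :func:`find_canonical_sites`, not here.
    """
    seq = _to_dna(transcript)
    motifs = bulged_site_strings(mirna, bulge_position, allowed_bases)
    canonical = [(h.start, h.end) for h in find_canonical_sites(seq, mirna)]
    hits: list[SiteHit] = []
    for base, motif in sorted(motifs.items()):
        for p in _find_all(seq, motif):
            window = (p, p + len(motif))
            if any(window[0] <= cs and ce <= window[1] for cs, ce in canonical):
                continue
            hits.append(
                SiteHit(
                    transcript_id=transcript_id,
                    start=p,
                    end=p + len(motif),
                    site_type="bulged",
                    inserted_base=base,
                    score=duplex_score(mirna, seq[p : p + len(motif)]),
                )
            )
    hits.sort(key=lambda h: (h.start, h.inserted_base or ""))
    return hits


def _pair_score(mi: str, tb: str) -> float:
    # mi: miRNA base (RNA), tb: target base (RNA); antiparallel opposition
    if (mi, tb) in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
        return SCORE_WC
    if (mi, tb) in (("G", "U"), ("U", "G")):
        return SCORE_WOBBLE
    return SCORE_MISMATCH


def duplex_score(
    mirna: Mirna,
    transcript_window: str,
    bulge_open_penalty: float = BULGE_OPEN_PENALTY,
    max_bulges: int = 1,
) -> float:
    """Simplified stability score of the miRNA:window duplex.

    The full miRNA is aligned antiparallel and gapless against the window at
    the offset maximising the score; opposed positions contribute +2 for a
    Watson-Crick pair, +1 for a G:U wobble and -1 for a mismatch. Up to
    ``max_bulges`` window bases may additionally be looped out of the duplex,
    each paying ``bulge_open_penalty``. Overhanging bases are unscored.
    A surrogate for hybridisation energy, not a thermodynamic MFE.
    """
    if not transcript_window:
        raise ValueError("transcript window is empty")
    seed_len = mirna.seed_end - mirna.seed_start
    if len(transcript_window) < seed_len:
        raise ValueError(
            f"window shorter than the seed ({len(transcript_window)} < {seed_len})"
        )
    if max_bulges not in (0, 1):
        raise ValueError("max_bulges must be 0 or 1")
    m = mirna.sequence
    rw = _to_dna(transcript_window).replace("T", "U")[::-1]  # 3'->5' becomes left-to-right
    M, W = len(m), len(rw)
    P = np.empty((M, W))
    for i, mi in enumerate(m):
        for k, tb in enumerate(rw):
            P[i, k] = _pair_score(mi, tb)

    # miRNA position i opposes rw position off + i; collect each offset's
    # opposed scores as a (padded) diagonal of P
    offsets = np.arange(-(M - 1), W)
    I = np.arange(M)
    K = offsets[:, None] + I[None, :]
    valid = (K >= 0) & (K < W)
    D = np.where(valid, P[I[None, :], np.clip(K, 0, W - 1)], 0.0)

    best = float(D.sum(axis=1).max())  # gapless
    if max_bulges >= 1 and len(offsets) > 1:
        # one looped-out window base between miRNA positions j-1 and j:
        # positions < j pair at offset o, positions >= j at offset o + 1
        cum = np.cumsum(D, axis=1)                     # cum[:, j-1] = sum_{i<j}
        tot = D.sum(axis=1)
        lo = cum[:-1, :-1]                             # offsets o, j = 1..M-1
        hi = tot[1:, None] - cum[1:, :-1]              # offsets o+1, tail i>=j
        bulged = float((lo + hi).max()) - bulge_open_penalty
        best = max(best, bulged)
    return float(best)


def annotate_interactome(
    calls: Sequence,
    transcripts: Mapping[str, str],
    mirna: Mirna = MIR16,
) -> pd.DataFrame:
    """Per-class site content of interactome calls.

    For every final label present among ``calls``, reports the fraction of
    genes (with an available transcript) carrying at least one canonical and
    at least one bulged site. Genes without a transcript are excluded from
    denominators; classes with no scannable gene get NaN fractions.

    Returns a DataFrame indexed by final_label with columns
    ``n_genes``, ``n_missing_transcript``, ``frac_canonical``, ``frac_bulged``.
    """
    rows: dict[str, dict[str, float]] = {}
    by_label: dict[str, list[str]] = {}
    for c in calls:
        by_label.setdefault(c.final_label, []).append(c.gene_id)
    for label, genes in sorted(by_label.items()):
        n_missing = sum(1 for g in genes if g not in transcripts)
        scanned = [g for g in genes if g in transcripts]
        n_can = sum(
            1 for g in scanned if find_canonical_sites(transcripts[g], mirna, g)
        )
        n_bul = sum(
            1 for g in scanned if find_bulged_sites(transcripts[g], mirna, g)
        )
        n = len(scanned)
        rows[label] = {
            "n_genes": n,
            "n_missing_transcript": n_missing,
            "frac_canonical": (n_can / n) if n else float("nan"),
            "frac_bulged": (n_bul / n) if n else float("nan"),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "final_label"
    return df


def hits_to_bed_frame(hits: Sequence[SiteHit]) -> pd.DataFrame:
    """BED6-like table of hits (name = site_type, optionally +inserted base)."""
    return pd.DataFrame(
        {
            "chrom": [h.transcript_id for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "name": [
                h.site_type if h.inserted_base is None
                else f"{h.site_type}:{h.inserted_base}"
                for h in hits
            ],
            "score": [h.score for h in hits],
            "strand": ["+" for _ in hits],
        }
    )
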