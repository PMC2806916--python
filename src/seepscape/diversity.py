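"""OTU clustering and richness estimation for clone libraries.

Sequences aligned over 500-600 bp are compared by uncorrected p-distance
(sites with a gap or ambiguity in either sequence excluded), clustered into
OTUs by furthest-neighbor (complete) linkage at a similarity threshold
(98% similarity == 0.02 distance), and summarized with the bias-corrected
Chao1 richness estimator

    S_chao1 = S_obs + n1 * (n1 - 1) / (2 * (n2 + 1))

where n1 and n2 are the numbers of singleton and doubleton OTUs. The
correction term vanishes when n1 <= 1, so the estimate never falls below
the observed count.
"""
from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from statistics import mean

import numpy as np

from .errors import DistanceError, ValidationError
from .io import Alignment, DistanceMatrixFile

_UNAMBIGUOUS = frozenset("ACGTU")


def similarity_to_distance(similarity_pct: float) -> float:
    """Map a percent similarity threshold to a distance cutoff (98 -> 0.02)."""
    if not 0 <= similarity_pct <= 100:
        raise ValidationError("similarity must be a percentage in [0, 100]")
    return 1.0 - similarity_pct / 100.0


def pairwise_pdistance(alignment: Alignment) -> DistanceMatrixFile:
    """Uncorrected pairwise p-distance matrix of an alignment.

    d(i, j) = mismatches / compared sites, where any site carrying a gap or
    an IUPAC ambiguity code in either sequence is dropped from both the
    numerator and the denominator. A pair with no comparable site at all is
    an error rather than a silent 0 or 1.
    """
    ids = alignment.ids
    seqs = [s.upper().replace("U", "T") for s in alignment.sequences]
    arrs = [np.frombuffer(s.encode(), dtype="S1") for s in seqs]
    valid = [np.isin(a, np.array([b"A", b"C", b"G", b"T"])) for a in arrs]
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        sites = int(both.sum())
        if sites == 0:
            raise DistanceError(f"no comparable sites between {ids[i]!r} and {ids[j]!r}")
        mism = int(np.count_nonzero(arrs[i][both] != arrs[j][both]))
        d[i, j] = d[j, i] = mism / sites
    return DistanceMatrixFile(list(ids), d)


@dataclass(frozen=True)
class OtuClustering:
    threshold: float
    assignments: dict[str, str]  # sequence id -> OTU id (smallest member label)
    sizes: dict[str, int]

    @property
    def n_otus(self) -> int:
        return len(self.sizes)

    def size_multiset(self) -> list[int]:
        return sorted(self.sizes.values())


def cluster_otus(d: DistanceMatrixFile, threshold: float) -> OtuClustering:
    """Agglomerative furthest-neighbor clustering cut at a distance threshold.

    Two clusters merge only if the *maximum* distance between any of their
    members is <= threshold, so every OTU is guaranteed a maximum intra-OTU
    distance within the threshold. Merges are processed in ascending order
    of complete-linkage distance; ties break on the lexicographically
    smallest (minimum member label) pair. OTU ids are the smallest member
    label of each final cluster.
    """
    if not 0 <= threshold <= 1:
        raise ValidationError("threshold must lie in [0, 1]")
    labels = d.labels
    dist = d.d
    clusters: list[list[int]] = [[i] for i in range(len(labels))]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            link = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            if link > threshold:
                continue
            key = (
                link,
                min(labels[i] for i in clusters[a] + clusters[b]),
                sorted(labels[i] for i in clusters[a] + clusters[b]),
            )
            if best is None or key < best[0]:
                best = (key, a, b)
        if best is None:
            break
        _, a, b = best
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    assignments: dict[str, str] = {}
    sizes: dict[str, int] = {}
    for members in clusters:
        otu_id = min(labels[i] for i in members)
        sizes[otu_id] = len(members)
        for i in members:
            assignments[labels[i]] = otu_id
    return OtuClustering(threshold, assignments, sizes)


@dataclass(frozen=True)
class RichnessEstimate:
    S_obs: int
    n1: int
    n2: int
    S_chao1: float
    sample_size: int


def chao1(sizes) -> RichnessEstimate:
    """Bias-corrected Chao1 richness from an OTU size multiset."""
    sizes = list(sizes)
    if not sizes:
        raise ValidationError("chao1 needs at least one OTU")
    if any(s < 1 or s != int(s) for s in sizes):
        raise ValidationError("OTU sizes must be positive integers")
    counts = Counter(int(s) for s in sizes)
    s_obs = len(sizes)
    n1, n2 = counts.get(1, 0), counts.get(2, 0)
    est = s_obs + n1 * (n1 - 1) / (2.0 * (n2 + 1))
    return RichnessEstimate(s_obs, n1, n2, est, sum(counts[k] * k for k in counts))


@dataclass(frozen=True)
class LibrarySizeQC:
    sample_id: str
    size: int
    deviation: float  # |size - mean| / size
    passed: bool


def library_size_qc(sizes: dict[str, int], max_deviation: float = 0.20) -> list[LibrarySizeQC]:
    """Flag clone libraries whose size deviates from the cohort mean.

    deviation_i = |size_i - mean| / size_i; a library passes iff its
    deviation is strictly below `max_deviation` (default 20%). Libraries
    should be QC'd per domain (bacteria vs. archaea) since target library
    sizes differ between amplicon sets.
    """
    if len(sizes) < 2:
        raise ValidationError("library-size QC needs at least two samples")
    if any(v <= 0 for v in sizes.values()):
        bad = [k for k, v in sizes.items() if v <= 0]
        raise ValidationError(f"zero-size libraries: {bad}")
    avg = mean(sizes.values())
    out = []
    for sample, size in sizes.items():
        dev = abs(size - avg) / size
        out.append(LibrarySizeQC(sample, size, dev, dev < max_deviation))
    return out
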