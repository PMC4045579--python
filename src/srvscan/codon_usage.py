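"""Codon-usage statistics: GC, GC3, ENC, CBI and TPI.

ENC follows Wright's estimator built from within-family homozygosities
averaged over degeneracy classes; CBI measures excess usage of a
declared optimal-codon set; TPI measures autocorrelation of
isoacceptor tRNA usage along the coding sequence, normalized linearly
between the minimal and maximal achievable number of tRNA switches for
each amino acid's label multiset.

All functions accept an in-frame nucleotide sequence; gap and ``N``
containing codons are skipped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .codes import GeneticCode, standard_code

__all__ = [
    "UsageIndices",
    "UndefinedIndexError",
    "gc_content",
    "gc3_content",
    "enc",
    "cbi",
    "tpi",
    "default_trna_mapping",
    "toy_optimal_codons",
    "compute_usage_indices",
    "min_switches",
    "max_switches",
    "count_switches",
]


class UndefinedIndexError(ValueError):
    """The index is undefined for this input (empty or degenerate)."""


@dataclass(frozen=True)
class UsageIndices:
    """Per-sequence codon-usage summary."""

    gc: float
    gc3: float
    enc: float
    cbi: float | None = None
    tpi: float | None = None


def _codons(seq: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise UndefinedIndexError("sequence length must be a multiple of 3")
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if set(codon) & {"-", "N"}:
            continue
        out.append(codon)
    return out


# ---------------------------------------------------------------------------
# Nucleotide composition
# ---------------------------------------------------------------------------


def gc_content(seq: str) -> float:
    """Fraction of G+C among non-gap bases."""
    bases = [b for b in seq.upper().replace("U", "T") if b in "ACGT"]
    if not bases:
        raise UndefinedIndexError("GC undefined for an empty sequence")
    return sum(b in "GC" for b in bases) / len(bases)


def gc3_content(seq: str) -> float:
    """GC fraction restricted to third codon positions."""
    thirds = [c[2] for c in _codons(seq)]
    if not thirds:
        raise UndefinedIndexError("GC3 undefined: no resolved codons")
    return sum(b in "GC" for b in thirds) / len(thirds)


# ---------------------------------------------------------------------------
# Effective Number of Codons (Wright's estimator)
# ---------------------------------------------------------------------------


def _degeneracy_classes(code: GeneticCode) -> dict[int, list[str]]:
    """Amino acids grouped by synonymous family size (1-fold excluded)."""
    classes: dict[int, list[str]] = {}
    for aa in code.amino_acids():
        fam = code.synonymous_family(aa)
        if len(fam) >= 2:
            classes.setdefault(len(fam), []).append(aa)
    return classes


def enc(
    data,
    mode: str = "counts",
    code: GeneticCode | None = None,
) -> float:
    """Wright's Effective Number of Codons.

    ``mode="counts"``: ``data`` is an in-frame sequence; per family the
    homozygosity is estimated as ``F = (n * sum p_i^2 - 1) / (n - 1)``
    from codon counts.  ``mode="frequencies"``: ``data`` maps codons to
    relative usage (any positive weights; normalized within family) and
    ``F = sum p_i^2`` directly.

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 with per-degeneracy-class mean
    homozygosities; families absent or observed fewer than twice are
    imputed by their size-class mean; a missing 3-fold class is imputed
    by the average of the 2- and 4-fold class means.  The result is
    clipped to [20, 61].
    """
    code = code or standard_code()
    classes = _degeneracy_classes(code)

    if mode == "counts":
        counts = Counter(_codons(data))
        fam_f: dict[int, list[float]] = {}
        for size, aas in classes.items():
            for aa in aas:
                fam = code.synonymous_family(aa)
                n_aa = sum(counts.get(c, 0) for c in fam)
                if n_aa < 2:
                    continue
                p = np.array([counts.get(c, 0) / n_aa for c in fam])
                f_hat = (n_aa * np.sum(p**2) - 1.0) / (n_aa - 1.0)
                fam_f.setdefault(size, []).append(f_hat)
    elif mode == "frequencies":
        freqs = {k.upper().replace("U", "T"): v for k, v in dict(data).items()}
        fam_f = {}
        for size, aas in classes.items():
            for aa in aas:
                fam = code.synonymous_family(aa)
                tot = sum(freqs.get(c, 0.0) for c in fam)
                if tot <= 0:
                    continue
                p = np.array([freqs.get(c, 0.0) / tot for c in fam])
                fam_f.setdefault(size, []).append(float(np.sum(p**2)))
    else:
        raise ValueError("mode must be 'counts' or 'frequencies'")

    if not fam_f:
        raise UndefinedIndexError("ENC undefined: no degenerate family observed")

    class_means = {size: float(np.mean(vals)) for size, vals in fam_f.items()}
    if 3 not in class_means:
        neighbours = [class_means[s] for s in (2, 4) if s in class_means]
        if neighbours:
            class_means[3] = float(np.mean(neighbours))
    # any other absent class: impute by the mean of available class means
    fallback = float(np.mean(list(class_means.values())))
    contributions = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}
    value = 2.0
    for size, numerator in contributions.items():
        f_bar = class_means.get(size, fallback)
        # guard against zero homozygosity (cannot happen with >=1 codon used)
        value += numerator / max(f_bar, 1e-12)
    return float(np.clip(value, 20.0, 61.0))


# ---------------------------------------------------------------------------
# Codon Bias Index
# ---------------------------------------------------------------------------


def cbi(
    seq: str,
    optimal: dict[str, frozenset[str] | set[str]],
    code: GeneticCode | None = None,
) -> float:
    """Codon Bias Index: (N_opt - N_rand) / (N_tot - N_rand).

    Counts run over codons of degenerate families that have at least
    one declared optimal codon; single-codon amino acids are excluded.
    ``N_rand`` is the expected number of optimal codons under uniform
    synonymous choice.  Ranges from -1 (only non-optimal codons) to +1
    (only optimal codons), 0 for random usage.
    """
    code = code or standard_code()
    for aa, codons in optimal.items():
        fam = set(code.synonymous_family(aa))
        if len(fam) < 2:
            raise UndefinedIndexError(
                f"optimal set declares single-codon amino acid {aa!r}"
            )
        if not set(codons) <= fam:
            raise UndefinedIndexError(
                f"optimal codons {sorted(set(codons) - fam)} do not encode {aa!r}"
            )
    n_opt = 0.0
    n_tot = 0.0
    n_rand = 0.0
    for codon in _codons(seq):
        aa = code.translate(codon)
        if aa == "*" or aa not in optimal:
            continue
        fam = code.synonymous_family(aa)
        if len(fam) < 2:
            continue
        n_tot += 1
        n_rand += len(optimal[aa]) / len(fam)
        if codon in optimal[aa]:
            n_opt += 1
    if n_tot == 0:
        raise UndefinedIndexError("CBI undefined: no codon from a covered family")
    if np.isclose(n_tot, n_rand):
        raise UndefinedIndexError("CBI undefined: degenerate normalization (N_tot = N_rand)")
    return float((n_opt - n_rand) / (n_tot - n_rand))


# ---------------------------------------------------------------------------
# tRNA Pairing Index
# ---------------------------------------------------------------------------


def default_trna_mapping(code: GeneticCode | None = None) -> dict[str, str]:
    """A wobble-based codon-to-tRNA mapping.

    Codons of the same amino acid sharing their first two bases are
    read by one tRNA when their third base is a pyrimidine (T/C wobble
    pairing); third-position A and G each get their own tRNA.  tRNA
    identifiers embed the amino acid, so different amino acids never
    share one.
    """
    code = code or standard_code()
    mapping = {}
    for codon in code.sense_codons:
        aa = code.translate(codon)
        third = codon[2]
        wobble = "Y" if third in "TC" else third
        mapping[codon] = f"tRNA-{aa}-{codon[:2]}{wobble}"
    return mapping


def count_switches(labels: list[str]) -> int:
    """Number of adjacent label changes along the sequence."""
    return sum(1 for a, b in zip(labels, labels[1:]) if a != b)


def min_switches(multiset: Counter) -> int:
    """Minimal switches: one contiguous block per distinct label."""
    return len(multiset) - 1


def max_switches(multiset: Counter) -> int:
    """Maximal achievable switches for a label multiset.

    With n items and largest multiplicity m, the alternation bound is
    ``min(2 * (n - m), n - 1)``.
    """
    n = sum(multiset.values())
    m = max(multiset.values())
    return min(2 * (n - m), n - 1)


def tpi(
    seq: str,
    mapping: dict[str, str] | None = None,
    code: GeneticCode | None = None,
) -> float:
    """tRNA Pairing Index: autocorrelation of tRNA usage, in [-1, 1].

    For each amino acid, the observed number of tRNA switches along its
    codon occurrence order is rescaled linearly between the minimal
    (+1, perfectly autocorrelated, e.g. XXXXYYYY) and maximal (-1,
    perfectly anticorrelated, e.g. XYXYXY) achievable switch counts;
    the index is the occurrence-weighted mean over amino acids whose
    bounds differ.
    """
    code = code or standard_code()
    mapping = mapping if mapping is not None else default_trna_mapping(code)
    per_aa: dict[str, list[str]] = {}
    for codon in _codons(seq):
        aa = code.translate(codon)
        if aa == "*":
            continue
        if codon not in mapping:
            raise UndefinedIndexError(f"no tRNA mapping for codon {codon}")
        per_aa.setdefault(aa, []).append(mapping[codon])

    scores, weights = [], []
    for aa, labels in per_aa.items():
        multiset = Counter(labels)
        if len(labels) < 2 or len(multiset) < 2:
            continue
        c_min = min_switches(multiset)
        c_max = max_switches(multiset)
        if c_max == c_min:
            continue
        c_obs = count_switches(labels)
        scores.append(1.0 - 2.0 * (c_obs - c_min) / (c_max - c_min))
        weights.append(len(labels))
    if not scores:
        raise UndefinedIndexError(
            "TPI undefined: no amino acid with >= 2 occurrences and >= 2 isoacceptors"
        )
    return float(np.average(scores, weights=weights))


# ---------------------------------------------------------------------------
# Convenience
# ---------------------------------------------------------------------------


def toy_optimal_codons(code: GeneticCode | None = None) -> dict[str, frozenset[str]]:
    """A deterministic optimal-codon set for tests and examples:
    the lexicographically first codon of every degenerate family."""
    code = code or standard_code()
    out = {}
    for aa in code.amino_acids():
        fam = code.synonymous_family(aa)
        if len(fam) >= 2:
            out[aa] = frozenset([sorted(fam)[0]])
    return out


def compute_usage_indices(
    seq: str,
    optimal: dict | None = None,
    mapping: dict[str, str] | None = None,
    code: GeneticCode | None = None,
) -> UsageIndices:
    """GC, GC3, ENC and (when inputs allow) CBI and TPI of one sequence."""
    code = code or standard_code()
    cbi_val = None
    if optimal is not None:
        try:
            cbi_val = cbi(seq, optimal, code)
        except UndefinedIndexError:
            cbi_val = None
    try:
        tpi_val = tpi(seq, mapping, code)
    except UndefinedIndexError:
        tpi_val = None
    return UsageIndices(
        gc=gc_content(seq),
        gc3=gc3_content(seq),
        enc=enc(seq, mode="counts", code=code),
        cbi=cbi_val,
        tpi=tpi_val,
    )
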