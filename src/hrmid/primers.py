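"""HRM primer candidate enumeration, screening and in-silico PCR.

Screening mirrors standard short-amplicon HRM design practice: a 20 +/- 2 bp
length window, a 40-60% GC window, products capped at 300 bp (long products
accumulate PCR errors and blur melt peaks), and structure screens that reject
hairpins and self-dimers. Structure screening uses longest-complementary-run
rules rather than thermodynamic folding:

* hairpin: a self reverse-complementary stem of >= ``hairpin_max_stem`` bases
  enclosing a loop of >= 3 bases;
* self-dimer: a contiguous inter-molecular complementary run of >=
  ``dimer_max_run`` bases; runs anchored at a 3' terminus are flagged
  separately at the tighter ``dimer_three_prime_run`` threshold, because a
  primed 3' end is extensible.

In-silico PCR finds all primer binding sites with a mismatch budget but an
exact 3'-terminal seed, and returns every amplicon spanned by a correctly
oriented site pair.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import RegionCall, consensus_sequence
from .records import BarcodeRecord

__all__ = [
    "PrimerConstraints",
    "PrimerPair",
    "Amplicon",
    "gc_content",
    "check_primer",
    "enumerate_pairs",
    "in_silico_pcr",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_AMBIGUITY = set("RYSWKMBDHVN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerConstraints:
    """Screening thresholds for HRM primer candidates."""

    len_min: int = 18
    len_max: int = 22
    gc_min: float = 0.40
    gc_max: float = 0.60
    product_max: int = 300
    hairpin_max_stem: int = 4
    hairpin_min_loop: int = 3
    dimer_max_run: int = 8
    dimer_three_prime_run: int = 5

    def __post_init__(self) -> None:
        if self.len_min > self.len_max:
            raise ValueError("len_min > len_max")
        if not 0 <= self.gc_min <= self.gc_max <= 1:
            raise ValueError("need 0 <= gc_min <= gc_max <= 1")
        if self.product_max <= 2 * self.len_max:
            raise ValueError("product_max must exceed two primer lengths")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse oligo pair on a template.

    ``rev`` is written 5'->3' on the reverse strand; coordinates are 0-based
    on the template with ``product_len = rev_end - fwd_start`` (both primer
    footprints included).
    """

    fwd: str
    rev: str
    fwd_start: int
    rev_end: int
    product_len: int
    verdict: tuple[str, ...] = ()  # empty tuple = pass

    def __post_init__(self) -> None:
        if self.product_len != self.rev_end - self.fwd_start:
            raise ValueError("product_len inconsistent with coordinates")

    @property
    def passed(self) -> bool:
        return not self.verdict


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product, both primer footprints included."""

    sequence: str
    start: int
    end: int  # 0-based half-open on the template
    fwd_mismatches: int = 0
    rev_mismatches: int = 0
    source_species: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)


def gc_content(seq: str) -> float:
    """Fraction (#G + #C) / length, ambiguity codes excluded from both."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    counted = sum(s.count(b) for b in "ACGT")
    if counted == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T bases")
    return (s.count("G") + s.count("C")) / counted


def _complementary_run_hits(seq: str, min_run: int):
    """All (i, j, k) with seq[i:i+k] == revcomp(seq[j:j+k]) and k == min_run.

    Brute-force scan over start pairs; primers are <= ~25 bp so O(n^2) is
    immaterial.
    """
    n = len(seq)
    k = min_run
    rc = revcomp(seq)  # rc[n-1-t] == complement(seq[t])
    hits = []
    for i in range(n - k + 1):
        for j in range(n - k + 1):
            # seq[i:i+k] pairs antiparallel with seq[j:j+k] iff
            # seq[i:i+k] == revcomp(seq[j:j+k]) == rc[n-j-k : n-j]
            if seq[i:i + k] == rc[n - j - k:n - j]:
                hits.append((i, j))
    return hits


def _has_hairpin(seq: str, min_stem: int, min_loop: int) -> bool:
    """Self reverse-complement stem >= min_stem with loop >= min_loop."""
    n = len(seq)
    k = min_stem
    for i in range(n - k + 1):
        stem5 = seq[i:i + k]
        for j in range(i + k + min_loop, n - k + 1):
            if stem5 == revcomp(seq[j:j + k]):
                return True
    return False


def check_primer(seq: str, constraints: PrimerConstraints | None = None) -> tuple[str, ...]:
    """Screen one oligo; returns a tuple of failure reasons (empty = pass).

    All failed checks are reported, not just the first. Case-insensitive.
    Degenerate IUPAC bases are rejected: the design pipeline emits ACGT only.
    """
    c = constraints or PrimerConstraints()
    s = seq.strip().upper()
    failures: list[str] = []
    if not s:
        return ("empty",)
    bad = set(s) - set("ACGT")
    if bad & _AMBIGUITY:
        failures.append(f"degenerate_bases:{''.join(sorted(bad & _AMBIGUITY))}")
    if bad - _AMBIGUITY:
        failures.append(f"illegal_characters:{''.join(sorted(bad - _AMBIGUITY))}")
    if failures:
        return tuple(failures)

    if not c.len_min <= len(s) <= c.len_max:
        failures.append(f"length:{len(s)} outside [{c.len_min},{c.len_max}]")
    gc = gc_content(s)
    if not c.gc_min <= gc <= c.gc_max:
        failures.append(f"gc:{gc:.2f} outside [{c.gc_min:.2f},{c.gc_max:.2f}]")
    if _has_hairpin(s, c.hairpin_max_stem, c.hairpin_min_loop):
        failures.append(f"hairpin:stem>={c.hairpin_max_stem}")

    n = len(s)
    for i, j in _complementary_run_hits(s, c.dimer_max_run):
        failures.append(f"self_dimer:run>={c.dimer_max_run}")
        break
    for i, j in _complementary_run_hits(s, c.dimer_three_prime_run):
        if i + c.dimer_three_prime_run == n or j + c.dimer_three_prime_run == n:
            failures.append(f"three_prime_dimer:run>={c.dimer_three_prime_run}")
            break
    return tuple(failures)


def enumerate_pairs(
    records: list[BarcodeRecord],
    regions: list[RegionCall],
    constraints: PrimerConstraints | None = None,
) -> list[PrimerPair]:
    """Enumerate passing primer pairs over an aligned panel's consensus.

    Forward oligos are windows inside one conserved region, reverse oligos
    (reverse-complemented) windows inside a downstream conserved region; the
    product must span at least one variable region and respect
    ``product_max``. Sorted by ascending product length, then by descending
    summed |GC - 0.5| of the two oligos.
    """
    c = constraints or PrimerConstraints()
    consensus = consensus_sequence(records)
    conserved = [r for r in regions if r.kind == "conserved"]
    variable = [r for r in regions if r.kind == "variable"]
    pairs: list[PrimerPair] = []

    for a_idx, ra in enumerate(conserved):
        for rb in conserved[a_idx + 1:]:
            spans_variable_possible = any(
                v.interval[0] >= ra.interval[0] and v.interval[1] <= rb.interval[1]
                for v in variable
            )
            if not spans_variable_possible:
                continue
            for flen in range(c.len_min, c.len_max + 1):
                for fs in range(ra.interval[0], ra.interval[1] - flen + 1):
                    fwd = consensus[fs:fs + flen]
                    if check_primer(fwd, c):
                        continue
                    for rlen in range(c.len_min, c.len_max + 1):
                        for rs in range(rb.interval[0], rb.interval[1] - rlen + 1):
                            re_ = rs + rlen
                            product_len = re_ - fs
                            if product_len > c.product_max:
                                continue
                            if not any(
                                v.interval[0] >= fs and v.interval[1] <= re_
                                for v in variable
                            ):
                                continue
                            rev = revcomp(consensus[rs:re_])
                            if check_primer(rev, c):
                                continue
                            pairs.append(
                                PrimerPair(fwd=fwd, rev=rev, fwd_start=fs,
                                           rev_end=re_, product_len=product_len)
                            )

    def sort_key(p: PrimerPair):
        off_center = abs(gc_content(p.fwd) - 0.5) + abs(gc_content(p.rev) - 0.5)
        return (p.product_len, -off_center)

    return sorted(pairs, key=sort_key)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _find_sites(primer_plus: str, template: str, max_mismatch: int,
                three_prime_exact: int, three_prime_at_end: bool):
    """All start positions where ``primer_plus`` binds the + strand.

    ``three_prime_at_end`` selects whether the oligo's 3' terminus sits at
    the end (forward primer) or the start (reverse primer footprint, which is
    the revcomp of the reverse oligo) of the + strand window.
    """
    lp = len(primer_plus)
    k = min(three_prime_exact, lp)
    sites = []
    for i in range(len(template) - lp + 1):
        window = template[i:i + lp]
        if three_prime_at_end:
            if window[lp - k:] != primer_plus[lp - k:]:
                continue
        else:
            if window[:k] != primer_plus[:k]:
                continue
        mm = _mismatches(window, primer_plus)
        if mm <= max_mismatch:
            sites.append((i, mm))
    return sites


def in_silico_pcr(
    fwd: str,
    rev: str,
    template: str | BarcodeRecord,
    max_mismatch: int = 0,
    three_prime_exact: int = 5,
    source_species: str = "",
) -> list[Amplicon]:
    """Predict all PCR products of a primer pair on an ungapped template.

    Each primer may carry up to ``max_mismatch`` mismatches but must match
    exactly over its ``three_prime_exact`` 3'-terminal bases. The forward 3'
    end must lie upstream of the reverse 3' end; the amplicon spans the
    forward 5' through the reverse 5' base, inclusive. No product is not an
    error: an empty list is returned.
    """
    if isinstance(template, BarcodeRecord):
        source_species = source_species or template.species_name
        template = template.sequence
    t = template.upper()
    if "-" in t:
        raise ValueError("template must be ungapped")
    f = fwd.upper()
    r = revcomp(rev.upper())  # reverse primer footprint on the + strand

    fwd_sites = _find_sites(f, t, max_mismatch, three_prime_exact, True)
    rev_sites = _find_sites(r, t, max_mismatch, three_prime_exact, False)

    products = []
    for fi, fmm in fwd_sites:
        fwd_three_prime = fi + len(f) - 1
        for rj, rmm in rev_sites:
            rev_three_prime = rj
            if fwd_three_prime < rev_three_prime:
                end = rj + len(r)  # reverse 5' base, half-open
                products.append(
                    Amplicon(sequence=t[fi:end], start=fi, end=end,
                             fwd_mismatches=fmm, rev_mismatches=rmm,
                             source_species=source_species)
                )
    products.sort(key=lambda a: (a.start, a.end))
    return products
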