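"""Ancestral-state polarization, unfolded SFS, and infinite-sites filtering.

The unfolded site frequency spectrum (SFS) counts, for each multiplicity class
i = 1..n-1, the segregating sites whose derived allele is carried by exactly i
of the n ingroup sequences.  Polarization uses one or two outgroup sequences
aligned to the same coordinates: where the outgroups agree and their state is
present in the ingroup, that state is taken as ancestral; otherwise the
ingroup major allele is used as a flagged fallback.

SFS-based estimators downstream assume the infinite sites model: every site
mutated at most once in the genealogy.  Without recombination this implies
that no pair of biallelic sites may show all four two-site gametes.
``infinite_sites_filter`` removes the minimal set of offending sites (rarer
minor allele first; ties broken toward the higher position) and reports which
haplotypes merge as a consequence.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import Alignment, HaplotypeTable, collapse_haplotypes, is_missing


@dataclass(frozen=True)
class AncestralEstimate:
    """Estimated ancestral sequence of the ingroup with per-site support."""

    sequence: str
    support: tuple[str, ...]  # 'both-outgroups-agree' | 'single-outgroup' | 'unresolved'

    def __post_init__(self):
        if len(self.sequence) != len(self.support):
            raise ValueError("support vector length differs from sequence length")

    @property
    def unresolved_positions(self) -> list[int]:
        return [i + 1 for i, s in enumerate(self.support) if s == "unresolved"]


@dataclass(frozen=True)
class SiteFrequencySpectrum:
    """Unfolded SFS: counts xi[i-1] of sites with derived-allele count i."""

    counts: tuple[int, ...]  # xi_1 .. xi_{n-1}
    n: int
    removed_sites: tuple[int, ...] = ()
    L_effective: int | None = None

    def __post_init__(self):
        if len(self.counts) != self.n - 1:
            raise ValueError("SFS must have n-1 classes")
        if any(c < 0 for c in self.counts):
            raise ValueError("negative SFS count")

    @property
    def S(self) -> int:
        return int(sum(self.counts))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("i\txi\n")
            for i, xi in enumerate(self.counts, start=1):
                fh.write(f"{i}\t{xi}\n")


def _major_allele(col: list[str]) -> str:
    """Most frequent non-missing state; count ties broken alphabetically."""
    counts = Counter(c for c in col if not is_missing(c))
    if not counts:
        raise ValueError("column is entirely missing")
    return min(counts, key=lambda b: (-counts[b], b))


def estimate_ancestral(ingroup: Alignment, outgroups: Alignment) -> AncestralEstimate:
    """Estimate the ingroup ancestral sequence from 1 or 2 outgroup sequences.

    Per site: if all non-missing outgroup states agree and that state occurs in
    the ingroup, it is ancestral (support 'both-outgroups-agree' with two
    informative outgroups, 'single-outgroup' with one).  Monomorphic ingroup
    sites take the ingroup state (polarization irrelevant).  Conflicting or
    ingroup-absent outgroup states fall back to the ingroup major allele with
    support 'unresolved'.
    """
    if outgroups.length != ingroup.length:
        raise ValueError(
            f"outgroup alignment length {outgroups.length} != ingroup {ingroup.length}")
    if outgroups.n not in (1, 2):
        raise ValueError("expected 1 or 2 outgroup sequences")
    anc = []
    support = []
    for pos in range(1, ingroup.length + 1):
        in_col = [c for c in ingroup.column(pos) if not is_missing(c)]
        in_states = set(in_col)
        out_states = [c for c in outgroups.column(pos) if not is_missing(c)]
        if len(in_states) <= 1:
            # monomorphic (or all-missing) ingroup site: outgroups irrelevant
            state = in_col[0] if in_col else "N"
            anc.append(state)
            support.append("both-outgroups-agree" if len(out_states) == 2
                           else "single-outgroup")
            continue
        distinct_out = set(out_states)
        if len(distinct_out) == 1 and out_states[0] in in_states:
            anc.append(out_states[0])
            support.append("both-outgroups-agree" if len(out_states) == 2
                           else "single-outgroup")
        else:
            anc.append(_major_allele(in_col))
            support.append("unresolved")
    return AncestralEstimate("".join(anc), tuple(support))


def unfolded_sfs(aln: Alignment, anc: AncestralEstimate,
                 removed_sites: tuple[int, ...] = ()) -> SiteFrequencySpectrum:
    """Build the unfolded SFS of an alignment polarized by ``anc``.

    Every segregating site must be biallelic and contain the ancestral state
    (run ``infinite_sites_filter`` first); a site whose derived allele count
    would be 0 or n indicates mispolarization and raises.
    """
    if len(anc.sequence) != aln.length:
        raise ValueError("ancestral sequence length differs from alignment")
    n = aln.n
    xi = [0] * (n - 1)
    for pos in range(1, aln.length + 1):
        col = [c for c in aln.column(pos) if not is_missing(c)]
        states = set(col)
        if len(states) <= 1:
            continue
        if len(states) > 2:
            raise ValueError(f"site {pos} has >2 states; filter before building SFS")
        a = anc.sequence[pos - 1]
        if a not in states:
            raise ValueError(f"ancestral state {a!r} absent at segregating site {pos}")
        derived = (states - {a}).pop()
        d = col.count(derived)
        if d == 0 or d == len(col):
            raise ValueError(f"site {pos} mispolarized (derived count {d})")
        # multiplicity class indexed against the full sample size n
        xi[d - 1] += 1
    return SiteFrequencySpectrum(tuple(xi), n, removed_sites=tuple(removed_sites),
                                 L_effective=aln.length)


# ---------------------------------------------------------------------------
# Infinite-sites compatibility


def _site_partition(aln: Alignment, pos: int) -> dict[str, list[int]]:
    """Record indices grouped by non-missing state at a 1-based position."""
    groups: dict[str, list[int]] = {}
    for idx, ch in enumerate(aln.column(pos)):
        if not is_missing(ch):
            groups.setdefault(ch, []).append(idx)
    return groups


def _four_gamete_violation(aln_matrix: np.ndarray, i: int, j: int) -> bool:
    """True when columns i, j (0-based) display all four two-site gametes."""
    a = aln_matrix[:, i]
    b = aln_matrix[:, j]
    ok = np.array([not is_missing(x) for x in a]) & \
        np.array([not is_missing(y) for y in b])
    pairs = set(zip(a[ok], b[ok]))
    return len(pairs) == 4


def _minor_count(aln: Alignment, pos: int) -> int:
    groups = _site_partition(aln, pos)
    return min(len(v) for v in groups.values())


def infinite_sites_filter(
        aln: Alignment) -> tuple[Alignment, list[int], dict[str, list[list[str]]]]:
    """Remove sites incompatible with the infinite sites model.

    Sites with more than two states are removed outright.  Then, while any
    pair of segregating sites shows all four gametes, the member of a violating
    pair with the rarer minor allele is removed (ties: higher position).
    Returns the filtered alignment, the removed 1-based positions (relative to
    the input alignment), and a haplotype merge report mapping pre-filter
    haplotype labels that collapsed together.
    """
    before = collapse_haplotypes(aln)
    removed: list[int] = []
    current = aln
    # pass 1: multi-state sites
    for pos in range(1, aln.length + 1):
        if len(_site_partition(aln, pos)) > 2:
            removed.append(pos)
    current = _remove_positions(aln, removed)
    # pass 2: four-gamete violations
    # positions tracked in input coordinates
    kept = [p for p in range(1, aln.length + 1) if p not in set(removed)]
    while True:
        mat = current.matrix()
        seg = [k for k, p in enumerate(kept)
               if len(_site_partition(current, k + 1)) >= 2]
        violation = None
        for ai in range(len(seg)):
            for bi in range(ai + 1, len(seg)):
                i, j = seg[ai], seg[bi]
                if _four_gamete_violation(mat, i, j):
                    violation = (i, j)
                    break
            if violation:
                break
        if violation is None:
            break
        i, j = violation
        mi = _minor_count(current, i + 1)
        mj = _minor_count(current, j + 1)
        if mi < mj:
            drop_local = i
        elif mj < mi:
            drop_local = j
        else:
            drop_local = max(i, j)  # tie: higher position
        removed.append(kept[drop_local])
        kept.pop(drop_local)
        current = _remove_positions(aln, removed)
    removed_sorted = sorted(removed)
    current = _remove_positions(aln, removed_sorted)
    merges = _merge_report(before, collapse_haplotypes(current))
    return current, removed_sorted, merges


def _remove_positions(aln: Alignment, positions: list[int]) -> Alignment:
    if not positions:
        return aln
    drop = set(p - 1 for p in positions)
    from dataclasses import replace
    records = tuple(
        replace(r, sequence="".join(ch for k, ch in enumerate(r.sequence)
                                    if k not in drop))
        for r in aln.records)
    return Alignment(records, window=aln.window)


def _merge_report(before: HaplotypeTable,
                  after: HaplotypeTable) -> dict[str, list[list[str]]]:
    """Groups of pre-filter haplotype labels that share a post-filter haplotype."""
    merged_groups = []
    for _label, _seq, _count, members in after.haplotypes:
        old_labels = sorted({before.label_of(m) for m in members})
        if len(old_labels) > 1:
            merged_groups.append(old_labels)
    return {"merged": merged_groups}


def removal_report_json(removed: list[int],
                        merges: dict[str, list[list[str]]]) -> str:
    return json.dumps({"removed_sites": removed, **merges}, indent=2)
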