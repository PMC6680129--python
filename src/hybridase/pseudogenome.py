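"""Coordinate-preserving pseudogenome construction.

The pseudogenome is the reference genome with the other species' allele
substituted at every fixed divergent site (FDS). Because only single-base
substitutions are applied, sequence names, order, lengths — and therefore all
genomic coordinates — are identical between reference and pseudogenome, which
is what lets alignments against the two be merged downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pyfaidx

from .sites import DivergentSite

_VALID = set("ACGT")


def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA into an ordered name → sequence dict (case preserved)."""
    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=False)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path: str, sequences: dict[str, str], width: int = 60) -> None:
    """Write sequences wrapped at `width` columns (fixed at 60 by default)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class PseudogenomeReport:
    """Outcome of comparing a pseudogenome against reference + site set."""

    n_compared: int
    matched: list[DivergentSite] = field(default_factory=list)
    missing: list[DivergentSite] = field(default_factory=list)   # site present, no substitution
    extra_diffs: list[tuple[str, int, str, str]] = field(default_factory=list)  # (chrom, pos1, ref, obs)

    @property
    def clean(self) -> bool:
        return not self.missing and not self.extra_diffs


def build_pseudogenome(
    reference: dict[str, str], sites: list[DivergentSite]
) -> dict[str, str]:
    """Substitute each site's alt allele into the reference.

    Soft-masked (lowercase) bases are substituted preserving case. A site
    whose ref allele does not match the reference base (including any
    non-ACGT base such as N) is an error; so is a duplicated position.
    """
    out = {name: bytearray(seq, "ascii") for name, seq in reference.items()}
    seen: set[tuple[str, int]] = set()
    mismatches: list[str] = []
    for s in sites:
        key = (s.chrom, s.pos)
        if key in seen:
            raise ValueError(f"duplicate divergent site at {s.chrom}:{s.pos}")
        seen.add(key)
        if s.chrom not in out:
            mismatches.append(f"{s.chrom}:{s.pos} (unknown sequence)")
            continue
        seq = out[s.chrom]
        if not 1 <= s.pos <= len(seq):
            mismatches.append(f"{s.chrom}:{s.pos} (outside sequence)")
            continue
        base = chr(seq[s.pos - 1])
        if base.upper() != s.ref_allele.upper() or base.upper() not in _VALID:
            mismatches.append(f"{s.chrom}:{s.pos} (ref {s.ref_allele}, found {base})")
            continue
        alt = s.alt_allele.upper() if base.isupper() else s.alt_allele.lower()
        seq[s.pos - 1] = ord(alt)
    if mismatches:
        raise ValueError(
            "reference allele mismatch at %d site(s): %s"
            % (len(mismatches), "; ".join(mismatches[:20]))
        )
    return {name: seq.decode("ascii") for name, seq in out.items()}


def swap_sites(sites: list[DivergentSite]) -> list[DivergentSite]:
    """Swap ref/alt alleles; building with swapped sites inverts a build."""
    return [
        DivergentSite(s.chrom, s.pos, s.alt_allele, s.ref_allele, s.qual) for s in sites
    ]


def validate_pseudogenome(
    reference: dict[str, str],
    pseudo: dict[str, str],
    sites: list[DivergentSite],
) -> PseudogenomeReport:
    """Report where pseudo differs from reference relative to the site set.

    ``extra_diffs`` is empty iff pseudo was produced by ``build_pseudogenome``
    from exactly these sites; ``missing`` holds sites whose substitution is
    absent.
    """
    if set(reference) != set(pseudo):
        raise ValueError("sequence name sets differ")
    for name in reference:
        if len(reference[name]) != len(pseudo[name]):
            raise ValueError(f"length mismatch for sequence {name}")
    by_pos = {(s.chrom, s.pos): s for s in sites}
    report = PseudogenomeReport(n_compared=sum(len(s) for s in reference.values()))
    for name in reference:
        ref_seq, p_seq = reference[name], pseudo[name]
        for i, (a, b) in enumerate(zip(ref_seq, p_seq)):
            if a == b:
                continue
            site = by_pos.get((name, i + 1))
            if site is not None and b.upper() == site.alt_allele.upper():
                report.matched.append(site)
            else:
                report.extra_diffs.append((name, i + 1, a, b))
    matched_keys = {(s.chrom, s.pos) for s in report.matched}
    report.missing = [s for s in sites if (s.chrom, s.pos) not in matched_keys]
    return report
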