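"""Flanking-sequence annotation for marker assay design.

Given a variant placed on a backbone with stored residues, the annotator
extracts a window of reference sequence on each side, renders the focal
variant as a bracketed allele block ("[REF/ALT,...]" — the assayable
alleles stay explicit) and substitutes every other known single-base
variant inside the window with the IUPAC ambiguity code of its reference
base united with its observed alleles.  Multi-base neighbours are left
untouched but listed with a skipped flag.  Sequences are always reported
on the + strand of the backbone.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import FlankingError, MissingRecordError
from .iupac import iupac_code
from .store import Store, split_allele_string

DEFAULT_WINDOW = 200


@dataclass(frozen=True)
class Substitution:
    """One neighbouring variant inside the window.

    ``position`` is the interbase fmin on the backbone; ``original`` the
    reference base(s) there; ``code`` the IUPAC character written into the
    sequence (None when skipped); ``skipped`` marks multi-base or
    non-ACGT neighbours left unsubstituted.
    """

    position: int
    original: str
    code: str | None
    skipped: bool = False


@dataclass
class FlankingSequence:
    """Annotated flanking sequence for one variant on one assembly."""

    variant: str
    backbone: str
    assembly: str
    window: int
    text: str
    focal_fmin: int
    focal_fmax: int
    focal_block: str  # e.g. "[A/G]"
    window_start: int  # interbase start of the extracted slice
    window_end: int
    substitutions: list = field(default_factory=list)

    def to_fasta(self) -> str:
        desc = (
            f">{self.variant} flank {self.backbone}:{self.window_start + 1}-{self.window_end} "
            f"assembly={self.assembly} focal={self.focal_block} "
            f"substitutions={len([s for s in self.substitutions if not s.skipped])}"
        )
        body = "\n".join(self.text[i : i + 80] for i in range(0, len(self.text), 80))
        return f"{desc}\n{body}\n"


def observed_alleles(store: Store, variant_id: int) -> set:
    """All alleles appearing in stored calls for a variant."""
    out: set = set()
    for (s,) in store.conn.execute(
        "SELECT DISTINCT g.allele_string FROM genotype_call gc "
        "JOIN genotype g ON g.genotype_id = gc.genotype_id WHERE gc.variant_id=?",
        (variant_id,),
    ):
        out.update(split_allele_string(s))
    return out


def flanking_sequence(
    store: Store,
    variant: str,
    assembly: str = "default",
    window: int = DEFAULT_WINDOW,
) -> FlankingSequence:
    """Build the annotated flanking sequence for a variant.

    Raises :class:`FlankingError` when the variant is not placed on the
    assembly or its backbone has no stored residues.  The window is
    truncated (never padded) at contig ends.
    """
    feat = store.feature_by_uniquename(variant)
    if feat is None:
        raise MissingRecordError(f"unknown variant {variant!r}")
    loc = store.conn.execute(
        "SELECT fl.fmin, fl.fmax, b.uniquename FROM featureloc fl "
        "JOIN feature b ON b.feature_id = fl.srcfeature_id "
        "WHERE fl.feature_id=? AND fl.assembly=? ORDER BY fl.featureloc_id LIMIT 1",
        (feat.feature_id, assembly),
    ).fetchone()
    if loc is None:
        raise FlankingError(f"variant {variant!r} is not placed on assembly {assembly!r}")
    fmin, fmax, backbone = loc
    residues = store.backbone_residues(backbone)
    if residues is None:
        raise FlankingError(f"backbone {backbone!r} has no stored residues")

    win_start = max(0, fmin - window)
    win_end = min(len(residues), fmax + window)
    ref_focal = residues[fmin:fmax]

    obs = observed_alleles(store, feat.feature_id)
    alts = sorted(a for a in obs if a != ref_focal)
    focal_block = "[" + "/".join([ref_focal, *alts]) + "]"

    # neighbouring variants with a location inside the window on this assembly
    neighbours = store.conn.execute(
        "SELECT fl.feature_id, fl.fmin, fl.fmax FROM featureloc fl "
        "JOIN feature v ON v.feature_id = fl.feature_id AND v.type='variant' "
        "JOIN feature b ON b.feature_id = fl.srcfeature_id "
        "WHERE b.uniquename=? AND fl.assembly=? AND fl.fmin >= ? AND fl.fmax <= ? "
        "AND fl.feature_id != ? ORDER BY fl.fmin",
        (backbone, assembly, win_start, win_end, feat.feature_id),
    ).fetchall()

    seq = list(residues[win_start:win_end])
    substitutions = []
    for nid, nmin, nmax in neighbours:
        if not (nmax <= fmin or nmin >= fmax):
            continue  # overlaps the focal block; leave to the bracket
        ref_base = residues[nmin:nmax]
        if nmax - nmin != 1:
            substitutions.append(Substitution(nmin, ref_base, None, skipped=True))
            continue
        alleles = {ref_base} | observed_alleles(store, nid)
        if not all(len(a) == 1 and a in "ACGT" for a in alleles):
            substitutions.append(Substitution(nmin, ref_base, None, skipped=True))
            continue
        code = iupac_code(alleles)
        seq[nmin - win_start] = code
        substitutions.append(Substitution(nmin, ref_base, code))

    left = "".join(seq[: fmin - win_start])
    right = "".join(seq[fmax - win_start :])
    return FlankingSequence(
        variant=variant,
        backbone=backbone,
        assembly=assembly,
        window=window,
        text=left + focal_block + right,
        focal_fmin=fmin,
        focal_fmax=fmax,
        focal_block=focal_block,
        window_start=win_start,
        window_end=win_end,
        substitutions=substitutions,
    )


def strip_annotations(flank: FlankingSequence) -> str:
    """Recover the reference substring from an annotated sequence.

    Replaces the focal bracket with its REF allele and reverts every
    applied substitution; byte-for-byte equal to the reference slice.
    """
    ref_focal = flank.focal_block[1:-1].split("/")[0]
    left_len = flank.focal_fmin - flank.window_start
    left = list(flank.text[:left_len])
    right_start = left_len + len(flank.focal_block)
    right = list(flank.text[right_start:])
    for sub in flank.substitutions:
        if sub.skipped:
            continue
        idx = sub.position - flank.window_start
        if idx < left_len:
            left[idx] = sub.original
        else:
            right[idx - left_len - (flank.focal_fmax - flank.focal_fmin)] = sub.original
    return "".join(left) + ref_focal + "".join(right)
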