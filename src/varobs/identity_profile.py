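"""Genotype fingerprinting to catch re-uploads of the same individual.

A profile is the ordered vector of genotype classes (hom-ref, het, hom-alt,
missing) over a fixed panel of common SNV sites.  Two profiles from the same
individual agree at essentially every site both cover; two unrelated
individuals agree far less often.  Similarity is the concordance fraction
over sites non-missing in both profiles, compared only when enough sites
overlap.  The default panel, threshold (0.95) and minimum overlap (10 sites)
are this package's own choices and are user-replaceable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

from .variant_model import Category, VariantRecord

HOM_REF = "R"
HET = "H"
HOM_ALT = "A"
MISSING = "."

DEFAULT_SIMILARITY_THRESHOLD = 0.95
DEFAULT_MIN_COMPARED = 10


class PanelError(ValueError):
    pass


@dataclass(frozen=True)
class SitePanel:
    """Ordered panel of (chrom, pos, ref, alt) profile sites."""

    sites: tuple[tuple[str, int, str, str], ...]

    @property
    def site_list_id(self) -> str:
        text = ";".join(f"{c}:{p}:{r}:{a}" for c, p, r, a in self.sites)
        return hashlib.sha1(text.encode()).hexdigest()[:12]

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class GenotypeProfile:
    site_list_id: str
    calls: tuple[str, ...]  # over {R, H, A, .}

    @property
    def n_missing(self) -> int:
        return sum(1 for c in self.calls if c == MISSING)

    @property
    def all_missing(self) -> bool:
        return self.n_missing == len(self.calls)


class SimilarityResult(NamedTuple):
    value: float
    n_compared: int
    insufficient: bool  # too few jointly covered sites to trust the value


def load_panel(path: str | Path) -> SitePanel:
    """Read a panel TSV: chrom, pos, ref, alt per line; '#' comments."""
    sites = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise PanelError(
                    f"{path}: line {lineno}: expected chrom, pos, ref, alt"
                )
            try:
                pos = int(cols[1])
            except ValueError as exc:
                raise PanelError(f"{path}: line {lineno}: bad position") from exc
            sites.append((cols[0], pos, cols[2].upper(), cols[3].upper()))
    if not sites:
        raise PanelError(f"{path}: empty panel")
    return SitePanel(tuple(sites))


def default_panel() -> SitePanel:
    with resources.as_file(
        resources.files("varobs").joinpath("data/profile_panel.tsv")
    ) as path:
        return load_panel(path)


def _classify(call) -> str:
    if "." in call.alleles or not call.alleles:
        return MISSING
    n_alt = sum(1 for a in call.alleles if a == "1")
    if n_alt == 0:
        return HOM_REF
    if n_alt == len(call.alleles) and len(call.alleles) == 2:
        return HOM_ALT
    return HET


def build_profiles(
    records: Iterable[VariantRecord], panel: SitePanel
) -> dict[str, GenotypeProfile]:
    """One profile per sample; panel sites absent from the input are missing."""
    site_index = {site: i for i, site in enumerate(panel.sites)}
    calls_by_sample: dict[str, list[str]] = {}
    for record in records:
        if record.category is Category.SV:
            continue
        idx = site_index.get((record.chrom, record.pos, record.ref, record.alt))
        if idx is None:
            continue
        for sample, call in record.genotypes.items():
            row = calls_by_sample.setdefault(sample, [MISSING] * len(panel))
            row[idx] = _classify(call)
    return {
        sample: GenotypeProfile(panel.site_list_id, tuple(row))
        for sample, row in calls_by_sample.items()
    }


def profile_similarity(
    p: GenotypeProfile,
    q: GenotypeProfile,
    min_compared: int = DEFAULT_MIN_COMPARED,
) -> SimilarityResult:
    """Concordance fraction over sites non-missing in both profiles.

    Returns value 0.0 flagged ``insufficient`` when fewer than
    ``min_compared`` sites are jointly covered.
    """
    if p.site_list_id != q.site_list_id:
        raise PanelError(
            f"profiles built on different panels "
            f"({p.site_list_id} vs {q.site_list_id})"
        )
    compared = matches = 0
    for a, b in zip(p.calls, q.calls):
        if a == MISSING or b == MISSING:
            continue
        compared += 1
        if a == b:
            matches += 1
    if compared < min_compared:
        return SimilarityResult(0.0, compared, True)
    return SimilarityResult(matches / compared, compared, False)
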