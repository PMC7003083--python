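"""Domain types and the threshold configuration of the screening pipeline.

Every numeric constant used anywhere in the pipeline lives in
:class:`Thresholds`, so a single plain-text config file fully determines a
run.  The taxonomy side is deliberately minimal: the pipeline does not talk
to any taxonomy database — group membership of reference species comes
solely from a user-supplied table (:class:`TaxonomyMap`), and the seven
group labels carry three boolean flags that drive every decision rule.

The "resident" clade defaults to arthropods inside metazoans (the setting
the method was benchmarked in), but nothing in the logic is
arthropod-specific: the flags generalize to any resident clade nested in an
enclosing clade, with five foreign source groups outside it.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping


class XenocdsError(Exception):
    """Base class for all errors raised by this package."""


class TaxonomyError(XenocdsError):
    """A species cannot be resolved against the taxonomy table."""


class ConfigError(XenocdsError):
    """Invalid threshold configuration."""


# --------------------------------------------------------------------------
# Taxonomic groups
# --------------------------------------------------------------------------

#: The five groups treated as potential sources of contamination and HGT.
FOREIGN_GROUP_NAMES = ("eubacteria", "archaea", "fungi", "viridiplantae", "protists")

#: All seven group labels the pipeline recognizes.
GROUP_NAMES = FOREIGN_GROUP_NAMES + ("arthropoda", "other_metazoa")


@dataclass(frozen=True)
class TaxGroup:
    """One taxonomic group with the membership flags the rules consume.

    ``is_arthropod`` marks the resident clade, ``is_metazoa`` its enclosing
    clade; ``is_foreign_source`` is true exactly for the five non-metazoan
    groups.
    """

    name: str
    is_metazoa: bool
    is_arthropod: bool
    is_foreign_source: bool

    def __post_init__(self) -> None:
        if self.is_arthropod and not self.is_metazoa:
            raise ConfigError(
                f"group {self.name!r}: resident clade must lie in the enclosing clade"
            )
        if self.is_foreign_source and self.is_metazoa:
            raise ConfigError(
                f"group {self.name!r}: a foreign source group cannot be metazoan"
            )


def _canonical_groups() -> Dict[str, TaxGroup]:
    groups = {}
    for name in FOREIGN_GROUP_NAMES:
        groups[name] = TaxGroup(name, is_metazoa=False, is_arthropod=False,
                                is_foreign_source=True)
    groups["arthropoda"] = TaxGroup("arthropoda", is_metazoa=True,
                                    is_arthropod=True, is_foreign_source=False)
    groups["other_metazoa"] = TaxGroup("other_metazoa", is_metazoa=True,
                                       is_arthropod=False, is_foreign_source=False)
    return groups


#: name -> TaxGroup for the seven canonical labels.
CANONICAL_GROUPS: Dict[str, TaxGroup] = _canonical_groups()


class TaxonomyMap:
    """Mapping from reference species identifiers to taxonomic groups.

    Lookup of an unknown species is an error, never a silent default: a
    reference database entry the pipeline cannot place would silently bias
    the hit fractions otherwise.
    """

    def __init__(self, species_to_group: Mapping[str, TaxGroup]):
        self._map: Dict[str, TaxGroup] = dict(species_to_group)

    def group_of(self, species: str) -> TaxGroup:
        try:
            return self._map[species]
        except KeyError:
            raise TaxonomyError(f"species {species!r} absent from taxonomy table") from None

    def __contains__(self, species: str) -> bool:
        return species in self._map

    def __len__(self) -> int:
        return len(self._map)

    def species(self) -> Iterable[str]:
        return self._map.keys()

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "TaxonomyMap":
        """Build from (species, group-name) pairs; duplicate species are an error."""
        out: Dict[str, TaxGroup] = {}
        for species, group_name in pairs:
            if species in out:
                raise TaxonomyError(f"species {species!r} listed twice in taxonomy table")
            if group_name not in CANONICAL_GROUPS:
                raise TaxonomyError(
                    f"unknown group {group_name!r} for species {species!r}; "
                    f"expected one of {', '.join(GROUP_NAMES)}"
                )
            out[species] = CANONICAL_GROUPS[group_name]
        return cls(out)

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyMap":
        """Read a two-column species<TAB>group table (no header, '#' comments)."""
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise TaxonomyError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                    )
                pairs.append((parts[0], parts[1]))
        return cls.from_pairs(pairs)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for species in sorted(self._map):
                fh.write(f"{species}\t{self._map[species].name}\n")


# --------------------------------------------------------------------------
# Category labels
# --------------------------------------------------------------------------

class Stage1(str, enum.Enum):
    """Similarity-based category of a CDS (first pipeline stage)."""

    CONFIDENT_ARTHROPOD = "confident_arthropod"
    OTHER_METAZOA = "other_metazoa"
    FOREIGN = "foreign"
    ORPHAN = "orphan"
    UNASSIGNED = "unassigned"


class Stage2(str, enum.Enum):
    """Synteny-based category of a foreign candidate (second pipeline stage)."""

    HGT_CANDIDATE = "hgt_candidate"
    CONTAMINANT_CANDIDATE = "contaminant_candidate"
    UNCERTAIN = "uncertain"
    NOT_APPLICABLE = "not_applicable"


# --------------------------------------------------------------------------
# Thresholds
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Thresholds:
    """Every numeric constant of the pipeline, with the published defaults.

    Hit filters are *strict* inequalities (identity > 40%, alignment length
    > 75 aa, E-value < 1e-10) exactly as worded; mapping and clustering
    filters are *inclusive* ("minimum alignment length of 100 bp", "minimum
    identity of 95%", "minimum of 60% of identity") because "minimum"
    denotes an attainable bound.  Input pre-filters discard scaffolds
    shorter than ``min_scaffold_len_bp`` and CDS shorter than
    ``min_cds_len_bp`` (i.e. lengths >= the bound are kept).
    """

    min_hit_identity_pct: float = 40.0     # hits kept iff identity > this
    min_hit_aln_len_aa: int = 75           # hits kept iff aln length (aa) > this
    max_hit_evalue: float = 1e-10          # hits kept iff evalue < this
    min_hits: int = 2                      # retained hits needed for assignment
    min_distinct_species: int = 2          # distinct species among retained hits
    top_n_hits: int = 10                   # best hits voted over
    majority_fraction: float = 0.70        # group fraction needed over the top hits
    confident_metazoa_fraction: float = 1.00   # enclosing-clade fraction for residents
    min_map_len_bp: int = 100              # mappings kept iff aln length >= this
    min_map_identity_pct: float = 95.0     # mappings kept iff identity >= this
    min_scaffold_len_bp: int = 200         # scaffolds kept iff length >= this
    min_cds_len_bp: int = 150              # CDS kept iff length >= this
    family_identity_fraction: float = 0.60  # family edges kept iff identity >= this
    logit_adjustment: float = 0.025        # squeeze applied to proportions at 0/1

    def __post_init__(self) -> None:
        for name in ("majority_fraction", "confident_metazoa_fraction",
                     "family_identity_fraction", "logit_adjustment"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        for name in ("min_hits", "min_distinct_species", "top_n_hits",
                     "min_map_len_bp", "min_scaffold_len_bp", "min_cds_len_bp",
                     "min_hit_aln_len_aa"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v}")
        if self.logit_adjustment >= 0.5:
            raise ConfigError("logit_adjustment must be < 0.5")
        if self.max_hit_evalue < 0:
            raise ConfigError("max_hit_evalue must be >= 0")

    _INT_FIELDS = ("min_hit_aln_len_aa", "min_hits", "min_distinct_species",
                   "top_n_hits", "min_map_len_bp", "min_scaffold_len_bp",
                   "min_cds_len_bp")

    def to_text(self) -> str:
        """Serialize as ``key = value`` lines (round-trips exactly)."""
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name} = {v!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Thresholds":
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"config line {lineno}: expected 'key = value', got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise ConfigError(f"config line {lineno}: unknown key {key!r}")
            try:
                parsed = int(value) if key in cls._INT_FIELDS else float(value)
            except ValueError as exc:
                raise ConfigError(f"config line {lineno}: bad value for {key}: {value!r}") from exc
            kwargs[key] = parsed
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def from_file(cls, path) -> "Thresholds":
        with open(path) as fh:
            return cls.from_text(fh.read())
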