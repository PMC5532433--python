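"""Stage parameter blocks and the flat-text pipeline configuration.

Each analysis stage takes a small frozen dataclass of parameters whose
defaults encode the study's published thresholds: 98% nucleotide identity and
70% shared nucleotides for species-level de-replication, a 70% completeness
floor, rpS3 length window 120-450 aa with per-domain bit-score cutoffs
(bacteria 111, archaea 172, eukaryotes 175), and a three-mismatch-per-100-bp
read-mapping stringency (97% similarity to the template).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


class ConfigError(ValueError):
    """Raised when a parameter leaves its documented legal range."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class DereplicationParams:
    """Species-level genome de-replication thresholds."""

    identity_threshold: float = 0.98
    shared_fraction_threshold: float = 0.70
    completeness_floor: float = 0.70
    anchor_k: int = 15

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "shared_fraction_threshold", "completeness_floor"):
            v = getattr(self, name)
            _check(0 < v <= 1, f"{name} must be in (0, 1], got {v}")
        _check(self.anchor_k >= 8, "anchor_k must be >= 8")


@dataclass(frozen=True)
class MarkerCutoffs:
    """rpS3 hit acceptance: length window and per-domain bit-score cutoffs."""

    min_len_aa: int = 120
    max_len_aa: int = 450
    score_cutoffs: dict = field(
        default_factory=lambda: {"bacteria": 111.0, "archaea": 172.0, "eukaryote": 175.0}
    )

    def __post_init__(self) -> None:
        _check(self.min_len_aa < self.max_len_aa, "min_len_aa must be < max_len_aa")
        _check(all(c > 0 for c in self.score_cutoffs.values()), "score cutoffs must be > 0")


@dataclass(frozen=True)
class MappingParams:
    """Stringent end-to-end read placement: <= floor(0.03 * L) mismatches."""

    max_mismatch_fraction: float = 0.03
    seed_kmer: int = 25
    presence_min_coverage: float = 1.0
    ambiguous_policy: str = "fractional"  # or "discard"

    def __post_init__(self) -> None:
        _check(0 <= self.max_mismatch_fraction < 0.1,
               "max_mismatch_fraction must be in [0, 0.1)")
        _check(self.ambiguous_policy in ("fractional", "discard"),
               "ambiguous_policy must be 'fractional' or 'discard'")

    def max_mismatches(self, read_len: int) -> int:
        return int(self.max_mismatch_fraction * read_len)


@dataclass(frozen=True)
class CrisprParams:
    """CRISPR repeat-spacer grammar windows (CRISPRfinder conventions)."""

    min_repeat_len: int = 23
    max_repeat_len: int = 55
    min_spacer_len: int = 25
    max_spacer_len: int = 60
    min_repeats: int = 3
    max_repeat_mismatches: int = 2
    type_min_shared_spacers: int = 2

    def __post_init__(self) -> None:
        _check(self.min_repeat_len <= self.max_repeat_len, "empty repeat length range")
        _check(self.min_spacer_len <= self.max_spacer_len, "empty spacer length range")
        _check(self.min_repeats >= 2, "min_repeats must be >= 2")


@dataclass(frozen=True)
class EcologyParams:
    """Permutation counts and NMDS settings for the community-ecology battery."""

    n_permutations: int = 999
    nmds_k: int = 2
    nmds_starts: int = 50
    nmds_max_iter: int = 200
    convergence_tol: float = 1e-6
    standardize_env: bool = True

    def __post_init__(self) -> None:
        _check(self.n_permutations >= 1, "n_permutations must be >= 1")
        _check(self.nmds_k >= 1, "nmds_k must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameter blocks plus the run seed and output directory."""

    dereplication: DereplicationParams = field(default_factory=DereplicationParams)
    marker_cutoffs: MarkerCutoffs = field(default_factory=MarkerCutoffs)
    mapping: MappingParams = field(default_factory=MappingParams)
    crispr: CrisprParams = field(default_factory=CrisprParams)
    ecology: EcologyParams = field(default_factory=EcologyParams)
    seed: int = 0
    outdir: Path = Path("halocrust_out")


_BLOCKS = {
    "derep": ("dereplication", DereplicationParams),
    "marker": ("marker_cutoffs", MarkerCutoffs),
    "mapping": ("mapping", MappingParams),
    "crispr": ("crispr", CrisprParams),
    "ecology": ("ecology", EcologyParams),
}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``block.key: value`` text config into a PipelineConfig.

    Lines are ``derep.identity_threshold: 0.98``; ``#`` starts a comment;
    unknown keys raise.  Top-level keys: ``seed``, ``outdir``.
    """
    overrides: dict[str, dict[str, object]] = {name: {} for name in _BLOCKS}
    top: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key: value'")
        key, value = (part.strip() for part in line.split(":", 1))
        if key == "seed":
            top["seed"] = int(value)
            continue
        if key == "outdir":
            top["outdir"] = Path(value)
            continue
        if "." not in key:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        block, param = key.split(".", 1)
        if block not in _BLOCKS:
            raise ConfigError(f"{path}:{lineno}: unknown block {block!r}")
        _, cls = _BLOCKS[block]
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        if param not in fields:
            raise ConfigError(f"{path}:{lineno}: unknown parameter {key!r}")
        overrides[block][param] = _coerce(value, getattr(cls(), param))
    kwargs: dict[str, object] = dict(top)
    for block, (attr, cls) in _BLOCKS.items():
        if overrides[block]:
            kwargs[attr] = dataclasses.replace(cls(), **overrides[block])
    return PipelineConfig(**kwargs)  # type: ignore[arg-type]


def _coerce(text: str, default: object) -> object:
    if isinstance(default, bool):
        return text.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(text)
    if isinstance(default, float):
        return float(text)
    if isinstance(default, dict):
        out = {}
        for item in text.split(","):
            k, v = item.split("=")
            out[k.strip()] = float(v)
        return out
    return text
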