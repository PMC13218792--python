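"""Run configuration: defaults, flat key=value config files, flag merging."""

from __future__ import annotations

from dataclasses import dataclass, fields

from .errors import InputError


@dataclass
class RunConfig:
    """Tunable parameters of the detection pipeline.

    Defaults follow the published workflow: junction ends within 250 nt
    and at least 2 supporting reads define a breakpoint; partner loci are
    displayed within a 50 kb half-window; regions are screened in blocks
    of at most 10 Mb; CIGAR indels longer than 10 bp are considered.
    """

    window: int = 250
    min_support: int = 2
    secondary_half_width: int = 50_000
    block_limit: int = 10_000_000
    indel_min_len: int = 10
    min_mapq: int = 0
    overlap_tol: int = 200
    seed: int = 0
    output_formats: tuple[str, ...] = ("tsv",)

    def __post_init__(self) -> None:
        for name in ("window", "min_support", "secondary_half_width",
                     "block_limit", "indel_min_len"):
            if getattr(self, name) <= 0:
                raise InputError(f"config: {name} must be positive")
        if self.min_mapq < 0 or self.overlap_tol < 0 or self.seed < 0:
            raise InputError("config: negative value not allowed")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Parse a flat ``key = value`` file ('#' starts a comment)."""
        values: dict = {}
        known = {f.name: f for f in fields(cls)}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise InputError(
                        f"{path}:{lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in known:
                    raise InputError(f"{path}:{lineno}: unknown key {key!r}")
                if key == "output_formats":
                    values[key] = tuple(v.strip()
                                        for v in value.split(",") if v)
                else:
                    values[key] = int(value)
        return cls(**values)

    def merged(self, **overrides) -> "RunConfig":
        """New config with non-None overrides applied (flags win)."""
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**current)
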