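"""Run configuration: per-SV-type clustering and filtering parameters.

The on-disk format is flat ``key = value`` text with one optional section
per SV type (``[DEL]``, ``[INS]``, ``[DUP]``, ``[INV]``).  Keys before the
first section set global extraction/pipeline options; section keys override
the per-type defaults.  Loading then dumping a config is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .hap_cluster import ClusterParams
from .hap_filter import FilterParams, FilterSet
from .sig_extract import SV_TYPES

__all__ = ["RunConfig", "default_cluster_params", "default_filter_params"]


def default_cluster_params() -> dict[str, ClusterParams]:
    return {
        "DEL": ClusterParams(F=500.0),
        "INS": ClusterParams(F=500.0),
        "DUP": ClusterParams(F=500.0),
        "INV": ClusterParams(F=600.0),
    }


def default_filter_params() -> dict[str, FilterParams]:
    return {sv_type: FilterParams() for sv_type in SV_TYPES}


@dataclass(slots=True)
class RunConfig:
    """All tunables of one calling run."""

    min_sv_size: int = 30
    merge_gap: int = 500
    min_report_size: int = 50
    split_enabled: bool = True
    haplotype_genotyping: bool = True
    cluster: dict[str, ClusterParams] = field(default_factory=default_cluster_params)
    filter: dict[str, FilterParams] = field(default_factory=default_filter_params)

    def is_haplotype_neutral(self) -> bool:
        """True when the configuration makes haplotype information inert.

        With SR = DR = 1 for every SV type and all six filter-scale
        parameters zero, haplotype labels cannot influence clustering or
        filtering; the caller then ignores HP tags end to end (no cluster
        disunion, allele-fraction genotyping), making a run on a tagged BAM
        identical to one on the same BAM with tags stripped.
        """
        return all(
            p.SR == 1.0 and p.DR == 1.0 for p in self.cluster.values()
        ) and all(p.is_neutral() for p in self.filter.values())

    # -- serialization -------------------------------------------------

    _GLOBAL_KEYS = (
        "min_sv_size",
        "merge_gap",
        "min_report_size",
        "split_enabled",
        "haplotype_genotyping",
    )
    _CLUSTER_KEYS = ("F", "CR", "SR", "DR")
    _FILTER_KEYS = (
        "H0",
        "HR0",
        "HomoR",
        "HomoSF",
        "HomoSR",
        "NonHomoSF",
        "NonHomoSR",
        "LowHRF",
        "LowHRR",
    )
    _SET_KEYS = ("FF", "FR", "FS")

    def to_text(self) -> str:
        lines = []
        for key in self._GLOBAL_KEYS:
            v = getattr(self, key)
            lines.append(f"{key} = {str(v).lower() if isinstance(v, bool) else v}")
        for sv_type in SV_TYPES:
            lines.append("")
            lines.append(f"[{sv_type}]")
            cp = self.cluster[sv_type]
            for key in self._CLUSTER_KEYS:
                lines.append(f"{key} = {getattr(cp, key)!r}")
            fp = self.filter[sv_type]
            for set_id in ("a", "b"):
                fs = getattr(fp, f"set_{set_id}")
                for key in self._SET_KEYS:
                    lines.append(f"{key}_{set_id} = {getattr(fs, key)!r}")
            for key in self._FILTER_KEYS:
                lines.append(f"{key} = {getattr(fp, key)!r}")
        return "\n".join(lines) + "\n"

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        cfg = cls()
        section: str | None = None
        overrides: dict[str | None, dict[str, str]] = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1].strip()
                if section not in SV_TYPES:
                    raise ValueError(
                        f"line {lineno}: unknown section [{section}]"
                    )
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            overrides.setdefault(section, {})[key] = value
        for key, value in overrides.get(None, {}).items():
            if key not in cls._GLOBAL_KEYS:
                raise ValueError(f"unknown global config key {key!r}")
            if key in ("split_enabled", "haplotype_genotyping"):
                if value.lower() not in ("true", "false"):
                    raise ValueError(f"config key {key!r} must be true/false")
                setattr(cfg, key, value.lower() == "true")
            else:
                setattr(cfg, key, int(value))
        for sv_type in SV_TYPES:
            sec = overrides.get(sv_type, {})
            cluster_kw = {}
            filter_kw = {}
            sets = {"a": {}, "b": {}}
            for key, value in sec.items():
                try:
                    num = float(value)
                except ValueError as exc:
                    raise ValueError(
                        f"config key {key!r} in [{sv_type}]: {exc}"
                    ) from exc
                if key in cls._CLUSTER_KEYS:
                    cluster_kw[key] = num
                elif key in cls._FILTER_KEYS:
                    filter_kw[key] = num
                elif key.endswith(("_a", "_b")) and key[:-2] in cls._SET_KEYS:
                    sets[key[-1]][key[:-2]] = num
                else:
                    raise ValueError(
                        f"unknown config key {key!r} in section [{sv_type}]"
                    )
            try:
                if cluster_kw:
                    cfg.cluster[sv_type] = replace(cfg.cluster[sv_type], **cluster_kw)
                fp = cfg.filter[sv_type]
                if sets["a"]:
                    filter_kw["set_a"] = replace(fp.set_a, **sets["a"])
                if sets["b"]:
                    filter_kw["set_b"] = replace(fp.set_b, **sets["b"])
                if filter_kw:
                    cfg.filter[sv_type] = replace(fp, **filter_kw)
            except ValueError as exc:
                raise ValueError(f"invalid value in section [{sv_type}]: {exc}") from exc
        return cfg

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_text(fh.read())
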