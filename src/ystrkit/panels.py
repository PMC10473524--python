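"""Y-STR kit panel definitions.

A :class:`KitPanel` declares the ordered locus set of a commercial Y-STR
multiplex, which loci are constitutively multi-copy (DYS385a/b is typed as
an unphased pair in every male), and named subsets.  Kit logic is data, not
code: the registry ships the PowerPlex Y23 definition and its 17-marker
Yfiler-compatible subset, and user panels can be registered alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class KitPanel:
    """Ordered locus definitions for a Y-STR typing kit.

    Parameters
    ----------
    name:
        Panel identifier, e.g. ``"PowerPlexY23"``.
    loci:
        Ordered locus names. Multi-copy markers appear once (``"DYS385"``
        stands for the unphased a/b pair).
    multi_copy:
        Subset of ``loci`` carrying two alleles per male.
    yfiler17_subset:
        Locus names of the 17-marker Yfiler-compatible view (the Y23 panel
        minus its six kit-specific loci).
    dys389_recoded:
        True once DYS389II has been replaced by the DYS389II.I difference
        encoding; guards against double recoding.
    """

    name: str
    loci: tuple[str, ...]
    multi_copy: frozenset[str] = field(default_factory=frozenset)
    yfiler17_subset: tuple[str, ...] = ()
    dys389_recoded: bool = False

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError(f"panel {self.name!r}: duplicate locus names")
        unknown = self.multi_copy - set(self.loci)
        if unknown:
            raise ValueError(f"panel {self.name!r}: multi_copy loci not in panel: {sorted(unknown)}")
        if not set(self.yfiler17_subset) <= set(self.loci):
            raise ValueError(f"panel {self.name!r}: yfiler17_subset not a subset of loci")

    def n_markers(self) -> int:
        """Marker count with each multi-copy locus counted twice."""
        return len(self.loci) + sum(1 for l in self.loci if l in self.multi_copy)

    def subset(self, loci: tuple[str, ...], name: str | None = None) -> "KitPanel":
        """Return a panel restricted to ``loci`` (order preserved from this panel)."""
        unknown = set(loci) - set(self.loci)
        if unknown:
            raise KeyError(f"loci not in panel {self.name!r}: {sorted(unknown)}")
        keep = tuple(l for l in self.loci if l in set(loci))
        return replace(
            self,
            name=name or f"{self.name}:subset",
            loci=keep,
            multi_copy=self.multi_copy & set(keep),
            yfiler17_subset=tuple(l for l in self.yfiler17_subset if l in set(keep)),
        )


# Six loci added by PowerPlex Y23 over the 17-marker Yfiler panel.
Y23_SPECIFIC_LOCI = ("DYS481", "DYS549", "DYS533", "DYS570", "DYS576", "DYS643")

_Y23_LOCI = (
    "DYS576", "DYS389I", "DYS448", "DYS389II", "DYS19", "DYS391", "DYS481",
    "DYS549", "DYS533", "DYS438", "DYS437", "DYS570", "DYS635", "DYS390",
    "DYS439", "DYS392", "DYS643", "DYS393", "DYS458", "DYS385", "DYS456",
    "YGATAH4",
)

POWERPLEX_Y23 = KitPanel(
    name="PowerPlexY23",
    loci=_Y23_LOCI,
    multi_copy=frozenset({"DYS385"}),
    yfiler17_subset=tuple(l for l in _Y23_LOCI if l not in Y23_SPECIFIC_LOCI),
)

YFILER17 = POWERPLEX_Y23.subset(POWERPLEX_Y23.yfiler17_subset, name="Yfiler17")

PANEL_REGISTRY: dict[str, KitPanel] = {
    "powerplex_y23": POWERPLEX_Y23,
    "yfiler17": YFILER17,
}


def get_panel(name: str) -> KitPanel:
    """Look up a registered panel by key (case-insensitive)."""
    try:
        return PANEL_REGISTRY[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown panel {name!r}; registered: {sorted(PANEL_REGISTRY)}"
        ) from None
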