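import numpy as np
import pandas as pd
import pytest

from ystrkit.datamodel import HaplotypeTable
from ystrkit.panels import POWERPLEX_Y23, KitPanel


def make_table(rows, loci, populations=None, multi_copy=(), panel_name="toy"):
    """Build a HaplotypeTable from a list of per-row allele lists.

    Cells may be float, None (missing) or tuple (multi-copy pair /
    duplication record).
    """
    panel = KitPanel(name=panel_name, loci=tuple(loci), multi_copy=frozenset(multi_copy))
    n = len(rows)
    populations = populations or ["pop1"] * n
    alleles = pd.DataFrame(
        [[_canon(v) for v in row] for row in rows], columns=list(loci), dtype=object
    )
    return HaplotypeTable([f"S{i + 1}" for i in range(n)], list(populations), alleles, panel)


def _canon(v):
    if v is None:
        return None
    if isinstance(v, tuple):
        return tuple(float(x) for x in v)
    return float(v)


@pytest.fixture
def y23_csv(tmp_path):
    """A small PowerPlex Y23 CSV: 4 males, 2 populations, one duplicated-allele
    haplotype (two DYS19 values), one microvariant, one missing cell."""
    loci = [l for l in POWERPLEX_Y23.loci if l != "DYS385"]
    base = {l: 12 for l in loci}
    rows = []
    for sid, pop in [("Q1", "Qatar"), ("Q2", "Qatar"), ("K1", "Kuwait"), ("K2", "Kuwait")]:
        row = {"SampleID": sid, "Population": pop, **{l: str(v) for l, v in base.items()}}
        row["DYS385"] = "13,17"
        row["DYS389II"] = "30"
        row["DYS389I"] = "13"
        rows.append(row)
    rows[1]["DYS19"] = "14,15"  # duplication record
    rows[2]["DYS458"] = "17.2"  # microvariant
    rows[3]["DYS456"] = "99"  # missing sentinel
    rows[3]["DYS390"] = "23"
    path = tmp_path / "toy_y23.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
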