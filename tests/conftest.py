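import numpy as np
import pandas as pd
import pytest

from ncycle import synthetic_community as sc

POLF = "TGCGAYCCSAARGCBGACTC"
POLR = "ATSGCCATCATYTCRCCGGA"


@pytest.fixture(scope="session")
def small_refs():
    """Six references: two unrelated lineages of three (chimera-detectable)."""
    return (sc.make_reference_set("nifH", 3, 120, 0.2, seed=11)
            + sc.make_reference_set("nosZ", 3, 120, 0.2, seed=99))


@pytest.fixture(scope="session")
def nifh_refs():
    return sc.make_reference_set("nifH", 4, 120, 0.25, seed=7)


def make_design(refs, read_depth=200, chimera_rate=0.0, frameshift_rate=0.0,
                crops=("ZM",), seed=5, **kwargs):
    taxa = [sc.TaxonSpec(r.id, {}, 1.0 / len(refs)) for r in refs]
    return sc.CommunityDesign(crops=list(crops), timepoints=["t0", "t1", "t2"],
                              taxa=taxa, read_depth=read_depth,
                              chimera_rate=chimera_rate,
                              frameshift_rate=frameshift_rate, seed=seed,
                              **kwargs)


def make_barcodes(design):
    bases = "ACGT"
    out = {}
    for i, (sample_id, _, _) in enumerate(design.samples()):
        code = []
        idx = i
        for _ in range(10):
            code.append(bases[idx % 4])
            idx //= 4
        out[sample_id] = "".join(code)
    return out


@pytest.fixture()
def barcode_sheet():
    def _build(barcodes, gene="nifH"):
        return pd.DataFrame([{"sample": s, "gene": gene, "barcode": b}
                             for s, b in barcodes.items()])
    return _build
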