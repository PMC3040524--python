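import pytest

from hapmapkit import DataKey, HapmapStore, StoreConfig
from hapmapkit import synthetic_data as sd


@pytest.fixture(scope="session")
def trio_bundle():
    """Two populations diverged at F=0.2, one with trios, over an LCT-like gene."""
    spec = sd.SimSpec(
        seed=11,
        divergence_F=0.2,
        missing_rate=0.05,
        n_snps=15,
        populations=(
            sd.PopulationSpec("CEU", 20, 4),
            sd.PopulationSpec("YRI", 20, 0),
        ),
        genes=(sd.GeneLayout("LCT", 136_550_000, 136_590_000, n_exons=5),),
    )
    return sd.simulate_truth(spec)


def build_store(bundle, root, *, minus_strand_fraction=0.0):
    """Write a bundle in mirror layout and ingest every slice of it."""
    mirror = root / "mirror"
    sd.write_bundle(bundle, mirror, minus_strand_fraction=minus_strand_fraction)
    store = HapmapStore(StoreConfig(cache_root=root / "cache", mirror_root=mirror))
    spec = bundle.spec
    for pspec in spec.populations:
        for kind in ("genotype", "frequency", "ld", "phased"):
            store.ensure_available(
                DataKey(kind, spec.phase, pspec.code, spec.chromosome, spec.build)
            )
        store.ensure_available(
            DataKey("pedigree", spec.phase, pspec.code, "ALL", spec.build)
        )
    return store


@pytest.fixture()
def trio_store(trio_bundle, tmp_path):
    return build_store(trio_bundle, tmp_path, minus_strand_fraction=0.3)
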