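import numpy as np
import pytest

import facryst as fc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_small_spec(
    size: int = 512,
    seed: int = 0,
    crystals=None,
    rbc_count: int = 0,
    oct_artifact: bool = False,
    noise_sd: float = 3.0,
    **tissue_kw,
):
    """Compact slide spec for fast unit tests."""
    tissue = fc.TissueSpec(axes=(0.40 * size, 0.33 * size), **tissue_kw)
    return fc.SynthSpec(
        height=size,
        width=size,
        tissue=tissue,
        crystals=crystals or [],
        rbc=fc.RbcSpec(count=rbc_count),
        oct_artifact=fc.OctSpec(enabled=oct_artifact),
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_slide_2048():
    """Default-geometry slide, ~1% planted content, no confounders."""
    spec = fc.content_slide_spec(
        0.01, size=2048, seed=11, rbc_count=0, oct_artifact=False
    )
    return fc.generate_slide(spec)


@pytest.fixture(scope="session")
def clean_pipeline_2048(clean_slide_2048):
    """Full pipeline output on the shared clean slide (computed once)."""
    slide = clean_slide_2048
    roi = fc.delineate_slice(slide.image)
    crystals = fc.segment_crystals(slide.image, roi)
    tissue = fc.segment_tissue(slide.image, roi)
    content = fc.compute_content(crystals, tissue, roi)
    return {"slide": slide, "roi": roi, "crystals": crystals, "tissue": tissue,
            "content": content}
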