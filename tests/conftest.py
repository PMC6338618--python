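import pytest

from revscreen import build_layout, generate_probe_set
from revscreen.simulate import generate_screen


@pytest.fixture(scope="session")
def small_probes():
    """4 up + 2 down signature probes, 33 controls, length 30, budget 3."""
    return generate_probe_set(4, 2, 33, length=30, max_mismatch=3, seed=7)


@pytest.fixture(scope="session")
def tiny_screen(small_probes, tmp_path_factory):
    """Error-free two-compound screen with one planted reverser."""
    workdir = tmp_path_factory.mktemp("tiny_screen")
    probes = small_probes
    effects = {g: -2.0 for g in probes.signature_up}
    effects |= {g: +2.0 for g in probes.signature_down}
    layout = build_layout(["HIT", "NULL"], replicates=3, dmso_per_plate=6)
    truth, synth = generate_screen(
        probes, layout, {"HIT": effects}, workdir / "fastq",
        reads_per_well=5000, error_rate=0.0, seed=11,
    )
    return {
        "probes": probes,
        "layout": layout,
        "truth": truth,
        "synth": synth,
        "fastq_dir": workdir / "fastq",
        "effects": effects,
    }
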