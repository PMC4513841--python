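import pytest

from negselect.simulate import PanelSpec


@pytest.fixture
def small_panel() -> PanelSpec:
    """Three genes x three genomes with coverages straddling the 0.80 cutoff."""
    return PanelSpec(
        genomes=["UTI89", "CFT073", "EDL933"],
        genes=[("relE", 300), ("mqsR", 297), ("ydaS", 230)],
        presence={
            ("relE", "CFT073"): 1.0,
            ("relE", "EDL933"): 0.79,
            ("mqsR", "UTI89"): 0.95,
            ("mqsR", "CFT073"): 0.50,
            ("ydaS", "EDL933"): 0.80,
        },
        identity=95.0,
        fragmentation=3,
    )
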