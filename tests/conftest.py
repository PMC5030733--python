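import pytest

from gravical import (
    BalanceState,
    LiquidSpec,
    TrueResponse,
    VirtualInstrument,
    builtin_default_classes,
)


@pytest.fixture()
def classes():
    return builtin_default_classes()


@pytest.fixture()
def serum(classes):
    return next(lc for lc in classes if lc.name == "serum")


@pytest.fixture()
def water(classes):
    return next(lc for lc in classes if lc.name == "water")


@pytest.fixture()
def dmso(classes):
    return next(lc for lc in classes if lc.name == "DMSO")


@pytest.fixture()
def ap_liquid():
    """Aluminum phosphate adjuvant suspension (ρ = 1.025 g/mL)."""
    return LiquidSpec("AP", 1.025, temperature=22.7)


def make_instrument(
    p=1.0,
    q=0.0,
    noise_cv=0.0,
    noise_floor_sd=0.0,
    tip_bias=(0.0,) * 8,
    resolution=0.1,
    seed=0,
):
    """Virtual instrument with explicit (default: silent and exact) noise."""
    return VirtualInstrument(
        response=TrueResponse(p=p, q=q),
        tip_bias=tip_bias,
        noise_cv=noise_cv,
        noise_floor_sd=noise_floor_sd,
        balance=BalanceState(resolution=resolution, rng_seed=seed + 1),
        rng_seed=seed,
    )


@pytest.fixture()
def noiseless_identity():
    return make_instrument()


@pytest.fixture()
def instrument_factory():
    return make_instrument
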