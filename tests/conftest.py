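from hypothesis import HealthCheck, settings

# property tests must behave identically on every run and machine
settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")
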