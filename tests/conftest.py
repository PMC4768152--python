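from hypothesis import settings

# one derandomised profile for the whole suite
settings.register_profile("ci", derandomize=True, max_examples=200, deadline=None)
settings.load_profile("ci")
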