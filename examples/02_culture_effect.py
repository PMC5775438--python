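"""How much does co-evolving culture hinder a cognitive specialist?

A single specialist (advantage +phi while culture is in its preferred state,
-phi otherwise) invades a generalist population whose culture switches state
at rate eta per generation.  We solve the coupled chain exactly and compare
with the culture-free baseline at matched parameters.
"""

from coculture import (
    CompositionState,
    LanguageModelParams,
    build_language_model,
    culture_effect_ratios,
    fixation_summary,
)

params = LanguageModelParams(N=500, phi=0.1, eta=0.1, alpha=1.0, beta=1.0)
model = build_language_model(params)

eps, t = fixation_summary(model, CompositionState(1, "+"))
prob_ratio, time_ratio = culture_effect_ratios(params)

print(f"N = {params.N}, phi = {params.phi}, eta = {params.eta}, "
      f"alpha = beta = 1, culture starts preferred")
print(f"fixation probability with culture: {eps:.5f}")
print(f"conditional fixation time:         {t:.1f} generations")
print(f"probability ratio vs no culture:   {prob_ratio:.3f}")
print(f"time ratio vs no culture:          {time_ratio:.3f}")
print()
print("At this moderate population size the switching culture cuts the")
print("specialist's fixation probability to about one third of its")
print("culture-free value — a real but far from prohibitive cost.")
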