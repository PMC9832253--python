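Synthetic example decision network.

Topology: perception drivers (Activity, Respondent type, Macrophyte species,
Macrophyte growth level) -> Perception -> Plant management option ->
ecological consequences (Light, Nutrient availability, Flow, Trophic cascade,
with Ecosystem and Nutrient loading as local context) -> Phytoplankton.

All CPTs here are SYNTHETIC stand-ins constructed by the package authors for
testing and illustration; they are not empirical or expert-elicited tables.
Edit or replace the TSV files (validated on load) to adapt the tool.
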