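Flow	Light	Nutrient availability	Trophic cascade	p_low	p_medium	p_high
low	low	low	weak	0.5	0.3175744762	0.1824255238
low	low	low	strong	0.7310585786	0.1930832413	0.07585818002
low	low	high	weak	0.1418510649	0.2837064183	0.5744425168
low	low	high	strong	0.3100255189	0.3581622533	0.3318122278
low	high	low	weak	0.2314752165	0.3429673003	0.4255574832
low	high	low	strong	0.4501660027	0.3356689804	0.214165017
low	high	high	weak	0.04742587318	0.1349996506	0.8175744762
low	high	high	strong	0.119202922	0.2583377468	0.6224593312
high	low	low	weak	0.6899744811	0.2189025579	0.09112296101
high	low	low	strong	0.8581489351	0.1062798756	0.03557118927
high	low	high	weak	0.2689414214	0.3535179098	0.3775406688
high	low	high	strong	0.5	0.3175744762	0.1824255238
high	high	low	weak	0.4013123399	0.3489477657	0.2497398944
high	high	low	strong	0.6456563062	0.2452468726	0.1090968212
high	high	high	weak	0.09975048912	0.2320617387	0.6681877722
high	high	high	strong	0.2314752165	0.3429673003	0.4255574832
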