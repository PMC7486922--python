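# One synthetic state (5 CRDs x 6 counties), 24 years, full-season forecast.
# Train on the first 20 years, test on the last 4, canonical 10 channels,
# pair augmentation on, random search over 8 hyperparameter draws.
n_states: 1
crds_per_state: 5
counties_per_crd: 6
years: [1993, 1994, 1995, 1996, 1997, 1998, 1999, 2000, 2001, 2002, 2003,
        2004, 2005, 2006, 2007, 2008, 2009, 2010, 2011, 2012, 2013, 2014,
        2015, 2016]
detrend: percentage
base_year: 2013
variables: canonical10
augment: true
budget: 8
search_epochs: 5
final_epochs: 20
cutoffs: [nov]
seed: 1
outdir: maizecast_run
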