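{
 "synthetic_study_topology.nwk": "47e0f59e74c52a08559b106cfa366ae72dfdddec6c367da217729f8f81841312",
 "synthetic_study_matrix.csv": "586afc610c901ee52010f143075c76c8ec8c12a3087768c22db9d93506f65c6c",
 "synthetic_age_constraints.tsv": "fb5d637a979f2ac4442647a0750d01f51af75d3320729eba8a217d1ef55c7368"
}
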