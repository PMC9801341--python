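intervention_name	outcome_name	primary_reason	quality	source	section
Periconceptual folic acid fortification	Child mortality due to neural tube defects	no_outcome_proportion_data	very_low	Blencowe et al., 2018	wra_pw
Zinc fortification	Preterm birth	no_significant_effect	low	Carducci et al., 2021	wra_pw
Omega-3 fatty acid supplementation	Preterm birth	no_significant_effect	moderate	Middleton, 2018	wra_pw
Vitamin D supplementation	Preterm birth	no_significant_effect	low	Palacios et al., 2018	wra_pw
Stop smoking education	Preterm birth	unable_to_model	moderate	Chamberlain et al., 2017	wra_pw
Deworming	Maternal anaemia	no_significant_effect	low	Salam et al., 2021	wra_pw
Calcium supplementation	Pre-eclampsia	double_counted_elsewhere	low	Hofmeyr et al., 2018	wra_pw
Thiamine supplementation	Neonatal mortality	no_systematic_review	NA	NA	wra_pw
Nutrition sensitive agriculture intervention	Appropriate complementary feeding	no_standard_definition	very_low	Margolies et al., 2022	infants_children
Provision of SQ-LNS	Child anaemia	no_mortality_link	moderate	Wessells et al., 2021	infants_children
Multiple micronutrient powder	Child anaemia	no_mortality_link	moderate	Suchdev et al., 2020; De-regil et al., 2017	infants_children
Iron fortification	Child anaemia	no_mortality_link	very_low	Keats et al., 2019	infants_children
Deworming	Wasting	no_significant_effect	very_low	Thayer et al., 2017	infants_children
Prophylactic antibiotics	Stunting	no_systematic_review	NA	NA	infants_children
Vitamin D supplementation	Pneumonia incidence	no_significant_effect	low	Martineau et al., 2017	infants_children
Vitamin D supplementation	Stunting	no_significant_effect	low	Huey et al., 2020	infants_children
Neonatal zinc supplementation	Neonatal mortality due to sepsis	small_sample	very_low	Irfan et al., 2022	infants_children
Zinc for treatment of sepsis	Neonatal mortality due to sepsis	small_sample	very_low	Irfan et al., 2022	infants_children
Provision of SQ-LNS	Child mortality	no_direct_estimate	moderate	Stewart et al., 2020	infants_children
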