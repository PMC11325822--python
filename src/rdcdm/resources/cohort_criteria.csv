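domain,min_age_years,window_start,window_end,icd10_patterns,reported_n_patients
endocrinology,18,2015-01-01,2022-12-31,E05.-;E06.1;E03.-;E89.0;E06.3;E23.0;D86.-;D35.2,41559
gastroenterology,18,2015-01-01,2022-12-31,B15.-;B16.-;B17.-;B18.-;E83.0;E83.1;E88.0,1324
pneumonology,18,2015-01-01,2022-12-31,C34.-;A15.-;D86.-;J10.-,17141
hematology,18,2015-01-01,2022-12-31,C92.0,1673
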