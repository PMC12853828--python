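# Population benchmark margins, percent of the population aged 16+.
# Sources: official population figures as of 31 Dec 2023 (sex, age, BIK
# class, federal state); Microcensus 2021 (education by Casmin class,
# citizenship, household size).
# The published low-education margin appears both as 33.6 (tabulated) and
# 34.2 (text); the tabulated value is used here and the variant recorded in
# the note column.
characteristic,level,benchmark_pct,note
sex,male,49.0,
sex,female,51.0,
age,16-29,17.8,
age,30-39,15.5,
age,40-49,14.4,
age,50-59,17.2,
age,60-69,16.1,
age,70+,19.0,
bik,1,10.8,<20k inhabitants
bik,2,34.6,20k-<50k or surroundings 50k-<500k
bik,3,26.8,core city 50k-<500k or surroundings 500k+
bik,4,27.9,core city 500k+
state,Schleswig-Holstein,3.5,
state,Hamburg,2.2,
state,Lower Saxony,9.6,
state,Bremen,0.8,
state,North Rhine-Westphalia,21.4,
state,Hesse,7.6,
state,Rhineland-Palatinate,4.9,
state,Baden-Wuerttemberg,13.3,
state,Bavaria,15.8,
state,Saarland,1.2,
state,Berlin,4.5,
state,Brandenburg,3.1,
state,Mecklenburg-Western Pomerania,2.0,
state,Saxony,4.9,
state,Saxony-Anhalt,2.6,
state,Thuringia,2.5,
education,low,33.6,variant 34.2 also published for this margin
education,medium,46.3,
education,high,20.1,
citizenship,yes,85.0,German citizenship
citizenship,no,15.0,
household,single,24.9,single-person household
household,multi,75.1,
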