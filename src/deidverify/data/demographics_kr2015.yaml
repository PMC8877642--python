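# Demographic probability tables for the synthetic Korean EHR cohort
# generator, transcribed from published national statistics (family-name
# registry, 2015 Population and Housing Census, Red Cross blood statistics,
# MOHW smoking rate). Percentages are kept as printed; vectors that do not
# sum to exactly 100 are renormalized proportionally at load time.
version: kr2015-v1

# Leading family names (%): 20 named + one residual bucket for the ~98
# remaining names. Sums to 100.00.
family_names:
  Kim: 21.56
  Lee: 14.74
  Park: 8.46
  Jung: 4.86
  Choi: 4.72
  Jo: 2.93
  Kang: 2.56
  Yoon: 2.06
  Jang: 2.06
  Im: 2.05
  Shin: 1.99
  Yoo: 1.94
  Han: 1.56
  Oh: 1.54
  Seo: 1.52
  Jeon: 1.51
  Kwon: 1.42
  Hwang: 1.41
  An: 1.38
  Song: 1.38
  Other: 18.35

# Decade age bands (%), [lower, upper, percent]. The open-ended ">100" band
# is realized as 100-109. Sums to 100.00.
age_bands:
  - [0, 9, 8.03]
  - [10, 19, 9.40]
  - [20, 29, 13.56]
  - [30, 39, 14.10]
  - [40, 49, 16.03]
  - [50, 59, 16.62]
  - [60, 69, 11.93]
  - [70, 79, 6.80]
  - [80, 89, 3.06]
  - [90, 99, 0.4]
  - [100, 109, 0.07]

# Provinces and metropolitan cities (%). Sums to 100.2 as printed.
regions:
  Seoul: 18.5
  Busan: 6.5
  Daegu: 4.7
  Incheon: 5.7
  Gwangju: 2.9
  Daejeon: 2.9
  Ulsan: 2.2
  Sejong: 0.7
  North Chungcheong: 3.1
  South Chungcheong: 4.2
  Gangwon: 2.9
  Gyeonggi: 26.1
  North Gyeongsang: 5.1
  South Gyeongsang: 6.4
  North Jeolla: 3.5
  South Jeolla: 3.5
  Jeju: 1.3

# Rh+ ABO blood types (%). Sums to 99.5 as printed (Rh- dropped at source).
blood_types:
  A: 34.0
  B: 26.6
  O: 27.5
  AB: 11.4

# Adult smoking rate (%).
smoking_rate: 21.5

# Five illnesses, uniformly distributed.
illnesses: [cold, headache, gastritis, body ache, bruise]
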