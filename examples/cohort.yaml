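# Synthetic-cohort configuration for `phototraits simulate --config`.
# Every key is optional; omitted keys keep the package defaults, which
# are the study conditions (179 users, 30-60 photos each, 64x64 images).
#
# Trait order everywhere: narcissism, life_satisfaction,
# loneliness_family, loneliness_social, loneliness_romantic.

n_users: 179
photos_per_user: [30, 60]   # uniform range; minimum must be >= 30
image_size: [64, 64]
likert_sd: 0.7              # item noise around the latent trait (1-5 scale)

trait_means: {narcissism: 2.8, life_satisfaction: 3.2,
              loneliness_family: 2.2, loneliness_social: 2.4,
              loneliness_romantic: 2.8}
trait_sds:   {narcissism: 0.65, life_satisfaction: 0.8,
              loneliness_family: 0.75, loneliness_social: 0.7,
              loneliness_romantic: 0.95}

trait_corr:
  - [1.00,  0.10,  0.00,  0.00,  0.00]
  - [0.10,  1.00, -0.35, -0.30, -0.25]
  - [0.00, -0.35,  1.00,  0.45,  0.40]
  - [0.00, -0.30,  0.45,  1.00,  0.40]
  - [0.00, -0.25,  0.40,  0.40,  1.00]

# The default effect matrix: [trait, feature channel, beta].  Beta is the
# trait-feature correlation on the standardised latent scale; strong
# effects (|beta| >= 0.2) are the ones the sign-recovery checks track.
effects:
  - [narcissism, people_share, 0.35]
  - [narcissism, one_faced_share, 0.35]
  - [narcissism, avg_n_faces, 0.12]
  - [narcissism, happiness, 0.12]
  - [life_satisfaction, happiness, 0.30]
  - [life_satisfaction, avg_n_faces, 0.12]
  - [loneliness_family, happiness, -0.30]
  - [loneliness_family, avg_n_faces, -0.12]
  - [loneliness_family, people_share, -0.12]
  - [loneliness_romantic, animal_share, 0.35]
  - [loneliness_romantic, warm_share, -0.35]
  - [loneliness_romantic, val_var, -0.35]
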