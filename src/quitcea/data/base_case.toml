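# Base-case parameters for the text-message smoking-cessation support model.
# Flat key = value; probabilities as fractions, costs in GBP (2009-10 prices).

# quit and relapse dynamics
control_quit_6m = 0.049          # 6-month quit probability, current practice
rr_quit = 2.20                   # relative risk of quitting with text support
rr_quit_ci_low = 1.80            # 95% CI of the quit relative risk
rr_quit_ci_high = 2.68
relapse_6_12 = 0.21              # relapse between 6 and 12 months
relapse_lifetime = 0.30          # lifetime relapse among 12-month quitters
background_quit_annual = 0.02    # spontaneous annual quit rate, both arms
lifetime_relapse_mode = "one_off"  # "one_off" at 12 months, or "spread" over 10y

# health-state values (utilities)
utility_lung_cancer = 0.58
utility_stroke = 0.48
utility_mi = 0.80
utility_copd = 0.73
utility_chd = 0.80
utility_smoker = 0.75            # disease-free smoker
utility_former = 0.78            # disease-free former smoker

# annual disease treatment costs (GBP/year)
cost_lung_cancer = 5921.0
cost_stroke = 2218.0
cost_mi = 2341.0
cost_copd = 997.0
cost_chd = 1144.0

# one-off intervention costs per enrolled smoker (GBP)
intervention_cost_per_smoker = 16.12
royalty_management_per_smoker = 0.0

# economics
discount_rate_cost = 0.035
discount_rate_effect = 0.035
cycle_length = 0.5               # years; fixed
horizon_age = 100.0              # lifetime horizon
wtp_grid_max = 4000.0            # CEAC willingness-to-pay grid (GBP/QALY)
wtp_grid_step = 50.0

# cohort mix observed in the trial
start_ages = [24, 35, 48]
age_weights = [0.30, 0.31, 0.39]
male_weight = 0.55
female_weight = 0.45
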