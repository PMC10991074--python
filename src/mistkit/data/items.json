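{
  "version": "1.0",
  "notes": [
    "Shared item registry for the built-in MIST banks. Items that belong to more than one bank are stored once; bank membership is given by the ordered id lists under 'banks'.",
    "a = 3PL discrimination, b = 3PL difficulty, c = guessing floor (fixed at 0.5 for all calibrated items).",
    "ega_dimension: 1 = US/international real news, 2 = government/conspiracy fake news, 3 = science/ideology fake news, 4 = politically charged US real news. Veracity for MIST-16 items follows the dimension content: dimensions 1 and 4 are real-news headlines, dimensions 2 and 3 are fake-news headlines.",
    "ega_loadings: standardized network loadings on dimensions 1-4."
  ],
  "items": [
    {"id": "MIST_14", "headline": "Government Officials Have Manipulated Stock Prices to Hide Scandals", "veracity": "fake", "a": 3.50, "b": 0.53, "c": 0.5, "ega_dimension": 2, "ega_loadings": [-0.05, 0.26, 0.06, -0.04]},
    {"id": "MIST_28", "headline": "The Corporate Media Is Controlled by the Military-industrial Complex: The Major Oil Companies Own the Media and Control Their Agenda", "veracity": "fake", "a": 2.69, "b": 0.06, "c": 0.5},
    {"id": "MIST_20", "headline": "New Study: Left-Wingers Are More Likely to Lie to Get a Higher Salary", "veracity": "fake", "a": 3.26, "b": -0.20, "c": 0.5, "ega_dimension": 3, "ega_loadings": [0.09, 0.05, 0.44, 0.01]},
    {"id": "MIST_34", "headline": "The Government Is Manipulating the Public's Perception of Genetic Engineering in Order to Make People More Accepting of Such Techniques", "veracity": "fake", "a": 3.42, "b": -0.25, "c": 0.5},
    {"id": "MIST_15", "headline": "Left-Wing Extremism Causes 'More Damage' to World Than Terrorism, Says UN Report", "veracity": "fake", "a": 2.34, "b": -0.40, "c": 0.5},
    {"id": "MIST_7", "headline": "Certain Vaccines Are Loaded with Dangerous Chemicals and Toxins", "veracity": "fake", "a": 2.57, "b": -0.45, "c": 0.5},
    {"id": "MIST_19", "headline": "New Study: Clear Relationship Between Eye Color and Intelligence", "veracity": "fake", "a": 2.00, "b": -0.55, "c": 0.5},
    {"id": "MIST_33", "headline": "The Government Is Knowingly Spreading Disease Through the Airwaves and Food Supply", "veracity": "fake", "a": 5.60, "b": -0.76, "c": 0.5, "ega_dimension": 2, "ega_loadings": [0.16, 0.40, 0.06, 0.00]},
    {"id": "MIST_10", "headline": "Ebola Virus 'Caused by US Nuclear Weapons Testing', New Study Says", "veracity": "fake", "a": 2.64, "b": -1.02, "c": 0.5},
    {"id": "MIST_13", "headline": "Government Officials Have Illegally Manipulated the Weather to Cause Devastating Storms", "veracity": "fake", "a": 2.86, "b": -1.30, "c": 0.5},
    {"id": "MIST_50", "headline": "Attitudes Toward EU Are Largely Positive, Both Within Europe and Outside It", "veracity": "real", "a": 3.12, "b": 0.38, "c": 0.5},
    {"id": "MIST_82", "headline": "One-in-Three Worldwide Lack Confidence in NGOs", "veracity": "real", "a": 2.22, "b": 0.31, "c": 0.5},
    {"id": "MIST_87", "headline": "Reflecting a Demographic Shift, 109 US Counties Have Become Majority Nonwhite Since 2000", "veracity": "real", "a": 2.25, "b": 0.14, "c": 0.5},
    {"id": "MIST_65", "headline": "International Relations Experts and US Public Agree: America Is Less Respected Globally", "veracity": "real", "a": 2.36, "b": -0.03, "c": 0.5},
    {"id": "MIST_60", "headline": "Hyatt Will Remove Small Bottles from Hotel Bathrooms by 2021", "veracity": "real", "a": 3.39, "b": -0.09, "c": 0.5, "ega_dimension": 1, "ega_loadings": [0.28, 0.03, 0.07, 0.10]},
    {"id": "MIST_73", "headline": "Morocco’s King Appoints Committee Chief to Fight Poverty and Inequality", "veracity": "real", "a": 2.43, "b": -0.14, "c": 0.5, "ega_dimension": 1, "ega_loadings": [0.35, 0.04, -0.01, 0.11]},
    {"id": "MIST_88", "headline": "Republicans Divided in Views of Trump’s Conduct, Democrats Are Broadly Critical", "veracity": "real", "a": 2.79, "b": -0.31, "c": 0.5},
    {"id": "MIST_53", "headline": "Democrats More Supportive than Republicans of Federal Spending for Scientific Research", "veracity": "real", "a": 2.12, "b": -0.37, "c": 0.5},
    {"id": "MIST_58", "headline": "Global Warming Age Gap: Younger Americans Most Worried", "veracity": "real", "a": 8.59, "b": -0.60, "c": 0.5},
    {"id": "MIST_99", "headline": "US Support for Legal Marijuana Steady in Past Year", "veracity": "real", "a": 2.26, "b": -0.83, "c": 0.5},
    {"id": "MIST_96", "headline": "US Hispanic Population Reached New High in 2018, But Growth Has Slowed", "veracity": "real", "ega_dimension": 1, "ega_loadings": [0.33, -0.12, -0.06, 0.10]},
    {"id": "MIST_92", "headline": "Taiwan Seeks to Join Fight Against Global Warming", "veracity": "real", "ega_dimension": 1, "ega_loadings": [0.24, 0.11, 0.08, 0.09]},
    {"id": "MIST_47", "headline": "About a Quarter of Large US Newspapers Laid off Staff in 2018", "veracity": "real", "ega_dimension": 1, "ega_loadings": [0.24, 0.06, -0.03, 0.00]},
    {"id": "MIST_31", "headline": "The Government Is Actively Destroying Evidence Related to the JFK Assassination", "veracity": "fake", "ega_dimension": 2, "ega_loadings": [0.00, 0.40, 0.00, 0.01]},
    {"id": "MIST_1", "headline": "A Small Group of People Control the World Economy by Manipulating the Price of Gold and Oil", "veracity": "fake", "ega_dimension": 2, "ega_loadings": [-0.06, 0.22, 0.05, -0.02]},
    {"id": "MIST_32", "headline": "The Government Is Conducting a Massive Cover-Up of Their Involvement in 9/11", "veracity": "fake", "ega_dimension": 2, "ega_loadings": [-0.10, 0.31, 0.13, 0.00]},
    {"id": "MIST_8", "headline": "Climate Scientists' Work Is 'Unreliable', a 'Deceptive Method of Communication'", "veracity": "fake", "ega_dimension": 3, "ega_loadings": [0.08, 0.09, 0.26, 0.00]},
    {"id": "MIST_16", "headline": "Left-Wingers Are More Likely to Lie to Get a Good Grade", "veracity": "fake", "ega_dimension": 3, "ega_loadings": [0.01, 0.10, 0.39, 0.05]},
    {"id": "MIST_70", "headline": "Majority in US Still Want Abortion Legal, with Limits", "veracity": "real", "ega_dimension": 4, "ega_loadings": [0.14, -0.04, 0.00, 0.38]},
    {"id": "MIST_74", "headline": "Most Americans Say It’s OK for Professional Athletes to Speak out Publicly about Politics", "veracity": "real", "ega_dimension": 4, "ega_loadings": [0.08, 0.00, 0.04, 0.32]},
    {"id": "MIST_94", "headline": "United Nations Gets Mostly Positive Marks from People Around the World", "veracity": "real", "ega_dimension": 4, "ega_loadings": [0.06, 0.02, 0.02, 0.30]}
  ],
  "banks": {
    "MIST-20": ["MIST_14", "MIST_28", "MIST_20", "MIST_34", "MIST_15", "MIST_7", "MIST_19", "MIST_33", "MIST_10", "MIST_13", "MIST_50", "MIST_82", "MIST_87", "MIST_65", "MIST_60", "MIST_73", "MIST_88", "MIST_53", "MIST_58", "MIST_99"],
    "MIST-8": ["MIST_14", "MIST_20", "MIST_7", "MIST_33", "MIST_50", "MIST_60", "MIST_88", "MIST_58"],
    "MIST-16": ["MIST_73", "MIST_96", "MIST_60", "MIST_92", "MIST_47", "MIST_33", "MIST_31", "MIST_14", "MIST_1", "MIST_32", "MIST_20", "MIST_8", "MIST_16", "MIST_70", "MIST_74", "MIST_94"]
  }
}
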